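import pytest

from palinsert.annotate import decompose
from palinsert.panel import PALI1_TSD_COPY
from palinsert.tsd import classify_truncation, detect_relic, find_tsd

from .oracles import brute_tsd


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestFindTsd:
    def test_printed_twelve_mer(self):
        call = find_tsd(
            "AAGGTTCCAAGGTTCCAATCAGAAAGTGAT", "TCAGAAAGTGATCCGGTTAACCGGTTAACC"
        )
        assert call.duplicated_sequence == "TCAGAAAGTGAT"
        assert call.match_length == 12
        assert call.mismatches == 0

    def test_random_windows_negative_control(self, rng):
        """Unrelated 30-mers should almost never share a >= 8-mer: the chance
        of a hit is about 23*23 start pairs x (1 + 8x3 near-misses) x 4^-8
        ~ 0.2 per pair, so a run of clean pairs is checked loosely."""
        hits = 0
        for _ in range(30):
            a = random_dna(rng, 30)
            b = random_dna(rng, 30)
            if find_tsd(a, b) is not None:
                hits += 1
        assert hits <= 10

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            a = random_dna(rng, int(rng.integers(10, 31)))
            b = random_dna(rng, int(rng.integers(10, 31)))
            got = find_tsd(a, b)
            want = brute_tsd(a, b)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert got.match_length == want[0]

    def test_panel_tsds_recovered_exactly(self, panel, panel_calls):
        """100% of planted target-site copies recovered with exact sequence
        at background rate 0."""
        for name in (
            "goat", "ibex", "sheep", "wildebeest", "addax", "gazelle",
            "tibetan_antelope",
        ):
            rec = panel.by_name(name)
            call = panel_calls[name][0]
            elem = next(a for a in rec.truth if a.feature_type == "element")
            flank5 = rec.sequence[call.query_start - 30 : call.query_start]
            flank3 = rec.sequence[elem.end : elem.end + 30]
            got = find_tsd(flank5, flank3)
            assert got is not None
            assert got.duplicated_sequence == PALI1_TSD_COPY
            assert got.mismatches == 0


class TestTruncation:
    def test_is1_copy_truncated_only_5prime(self, panel):
        rep = classify_truncation(PALI1_TSD_COPY, panel.pali1)
        assert (rep.truncated_5prime, rep.truncated_3prime) == (True, False)

    def test_is2_copies_truncated_both_sides(self, panel):
        eland = panel.pali2.allele_sequence("eland")
        copy = eland[2:13]
        rep = classify_truncation(copy, panel.pali2, allele="eland")
        assert (rep.truncated_5prime, rep.truncated_3prime) == (True, True)

    def test_full_template_untruncated(self, panel):
        rep = classify_truncation(panel.pali1.sequence, panel.pali1)
        assert (rep.truncated_5prime, rep.truncated_3prime) == (False, False)
        assert rep.retained_fraction == 1.0

    @pytest.mark.parametrize("k", range(1, 10))
    def test_leading_deletion_sets_exactly_5prime(self, panel, k):
        rep = classify_truncation(panel.pali1.sequence[k:], panel.pali1)
        assert rep.recognizable
        assert (rep.truncated_5prime, rep.truncated_3prime) == (True, False)

    def test_small_remnant_unrecognizable(self, panel):
        rep = classify_truncation(panel.pali1.sequence[-5:], panel.pali1)
        assert not rep.recognizable


class TestRelic:
    def test_addax_relic_between_third_and_fourth_triplet(self, panel, panel_calls):
        comp = decompose(
            panel_calls["addax"][0].inserted_sequence, panel.element, "reverse"
        )
        relic = detect_relic(comp, [panel.pali1, panel.pali2])
        assert relic is not None
        assert relic.template_name == "PALI1"
        assert relic.terminator_repeats_before == 3
        assert relic.terminator_repeats_after == 1
        assert relic.polya_interval[1] - relic.polya_interval[0] == 12

    def test_canonical_element_has_none(self, panel, element):
        comp = decompose(element.sequence, element, "forward")
        assert detect_relic(comp, [panel.pali1, panel.pali2]) is None

    def test_polya_of_exactly_ten_is_rejected(self, panel, element):
        """The stated bound is strict: a 10-nt poly-A run is not a relic."""
        seq = (
            element.monomer1
            + element.linker
            + element.monomer2
            + "AGC" * 3
            + "A" * 10
            + panel.pali1.sequence[:8]
            + "AGC"
        )
        comp = decompose(seq, element, "forward")
        assert detect_relic(comp, [panel.pali1, panel.pali2]) is None

    def test_min_polya_argument_is_strict(self, panel, element):
        comp = decompose(element.sequence, element, "forward")
        with pytest.raises(ValueError, match="strict"):
            detect_relic(comp, [panel.pali1], min_polya=10)
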