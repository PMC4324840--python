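import math

import numpy as np
import pytest

from palinsert.io_formats import CountMatrix
from palinsert.motifs import (
    MotifHit,
    element_unique_hits,
    pwm_from_counts,
    scan,
)

from .oracles import brute_pwm_hits, revcomp


def word_matrix(word, motif_id="m", depth=12):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((4, len(word)))
    for k, b in enumerate(word):
        counts[idx[b], k] = depth
    return CountMatrix(motif_id, counts)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestPwmFromCounts:
    def test_hand_computed_log_odds(self):
        m = CountMatrix("m", np.array([[10.0], [0.0], [0.0], [0.0]]))
        pwm = pwm_from_counts(m, pseudocount=0.5)
        assert pwm.log_odds[0, 0] == pytest.approx(math.log2((10.5 / 12) / 0.25))

    def test_uniform_counts_are_zero_bits(self):
        m = CountMatrix("m", np.full((4, 5), 3.0))
        pwm = pwm_from_counts(m)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_width_preserved(self, rng):
        for w in (4, 7, 12):
            m = CountMatrix("m", rng.integers(0, 9, size=(4, w)) + 1.0)
            assert pwm_from_counts(m).width == w

    def test_all_zero_column_rejected(self):
        m = CountMatrix("m", np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 0.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="all-zero"):
            pwm_from_counts(m)


class TestScan:
    def test_planted_word_single_hit(self, rng):
        word = "TTCACGGAA"
        pwm = pwm_from_counts(word_matrix(word))
        seq = random_dna(rng, 60)
        while word in seq or revcomp(word) in seq:
            seq = random_dna(rng, 60)
        planted = seq[:25] + word + seq[25:]
        hits = scan(planted, pwm)
        assert [(h.start, h.end, h.strand) for h in hits] == [(25, 25 + len(word), "+")]

    def test_strand_symmetry(self, rng):
        pwm = pwm_from_counts(word_matrix("GGATCCA"))
        for _ in range(10):
            seq = random_dna(rng, 80)
            fwd = {(h.start, h.end, h.strand) for h in scan(seq, pwm)}
            flipped = {
                (len(seq) - h.end, len(seq) - h.start, "+" if h.strand == "-" else "-")
                for h in scan(revcomp(seq), pwm)
            }
            assert fwd == flipped

    def test_matches_brute_force_window_scoring(self, rng):
        for _ in range(10):
            counts = CountMatrix("m", rng.integers(0, 13, size=(4, 8)) + 0.0)
            if (counts.counts.sum(axis=0) == 0).any():
                continue
            pwm = pwm_from_counts(counts)
            seq = random_dna(rng, 200)
            got = sorted(
                (h.start, h.end, h.strand, round(h.score, 6)) for h in scan(seq, pwm)
            )
            want = brute_pwm_hits(seq, pwm.log_odds.tolist(), pwm.threshold)
            assert got == want

    def test_windows_with_n_skipped(self):
        pwm = pwm_from_counts(word_matrix("ACGT"))
        hits = scan("ACGNACGT", pwm)
        assert [(h.start, h.strand) for h in hits if h.strand == "+"] == [(4, "+")]


class TestElementUnique:
    def _hit(self, motif, start, end):
        return MotifHit(motif, "s", start, end, "+", 10.0)

    def test_inside_only_is_element_unique(self):
        cls = element_unique_hits([self._hit("m", 110, 118)], [(100, 200)], (0, 400))
        assert cls["m"].category == "element_unique"

    def test_inside_and_outside_is_shared(self):
        hits = [self._hit("m", 110, 118), self._hit("m", 300, 308)]
        cls = element_unique_hits(hits, [(100, 200)], (0, 400))
        assert cls["m"].category == "shared"

    def test_two_to_one_enrichment_reported_shared(self):
        hits = [
            self._hit("m", 110, 118),
            self._hit("m", 150, 158),
            self._hit("m", 300, 308),
        ]
        cls = element_unique_hits(hits, [(100, 200)], (0, 400))
        assert cls["m"].category == "shared"
        assert cls["m"].enrichment == "2:1"

    def test_classification_is_a_partition(self, rng):
        motifs = ["a", "b", "c", "d"]
        hits = []
        for motif in motifs[:3]:
            for _ in range(int(rng.integers(0, 4))):
                s = int(rng.integers(0, 390))
                hits.append(self._hit(motif, s, s + 8))
        cls = element_unique_hits(hits, [(100, 200)], (0, 400), motif_ids=motifs)
        assert set(cls) == set(motifs)
        valid = {"element_unique", "shared", "background_only", "absent"}
        assert all(c.category in valid for c in cls.values())

    def test_element_outside_region_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            element_unique_hits([], [(500, 600)], (0, 400))

    def test_panel_element_words_unique(self, panel, panel_calls):
        """The motif words planted inside the element are element-unique in a
        carrier species and absent from an element-free species."""
        from importlib import resources

        from palinsert.io_formats import read_jaspar

        path = resources.files("palinsert.data").joinpath("synthetic_motifs.jaspar")
        pwms = [pwm_from_counts(m) for m in read_jaspar(path)]
        goat = panel.by_name("goat")
        elements = [
            (a.start, a.end) for a in goat.truth if a.feature_type == "element"
        ]
        hits = [h for p in pwms for h in scan(goat.sequence, p, "goat")]
        cls = element_unique_hits(hits, elements, (0, len(goat.sequence)))
        assert cls["stat_like"].category == "element_unique"
        assert cls["nfkb_like"].category == "element_unique"
        assert cls["sp1_like"].category == "background_only"
        cow = panel.by_name("cow")
        hits = [h for p in pwms for h in scan(cow.sequence, p, "cow")]
        cls = element_unique_hits(
            hits, [], (0, len(cow.sequence)), motif_ids=[p.motif_id for p in pwms]
        )
        assert cls["stat_like"].category == "absent"
        assert cls["sp1_like"].category == "background_only"
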