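import numpy as np
import pytest

from palinsert.annotate import (
    call_variants,
    classify_monomers,
    count_tandem_copies,
    decompose,
    orient_element,
    summarize_variant_sharing,
)
from palinsert.io_formats import reverse_complement


def mutate(seq, positions, rng):
    bases = list(seq)
    for p in positions:
        bases[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[bases[p]]
    return "".join(bases)


class TestOrientation:
    def test_consensus_is_forward(self, element):
        res = orient_element(element.sequence, element)
        assert res.orientation == "forward"
        # mirror symmetry of the two strand scores
        flipped = orient_element(reverse_complement(element.sequence), element)
        assert res.forward_score == flipped.reverse_score

    def test_panel_orientations(self, panel, panel_calls):
        goat = orient_element(panel_calls["goat"][0].inserted_sequence, panel.element)
        eland = orient_element(panel_calls["eland"][0].inserted_sequence, panel.element)
        assert goat.orientation == "reverse"
        assert eland.orientation == "forward"

    def test_unrelated_sequence_unrecognized(self, element, rng):
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        assert orient_element(junk, element).orientation == "unrecognized"


class TestDecompose:
    def test_canonical_component_widths(self, element):
        comp = decompose(element.sequence, element, "forward")
        widths = {k: b - a for k, (a, b) in comp.intervals.items()}
        assert widths == {
            "monomer1": 116,
            "linker": 27,
            "monomer2": 117,
            "terminator": 12,
        }
        assert comp.terminator_repeat_count == 4
        assert not comp.is_partial

    def test_intervals_tile_without_overlap(self, element):
        comp = decompose(element.sequence, element, "forward")
        ivs = sorted(comp.intervals.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ivs, ivs[1:]):
            assert a_hi <= b_lo

    def test_relic_excluded_from_terminator(self, panel, panel_calls):
        call = panel_calls["addax"][0]
        comp = decompose(call.inserted_sequence, panel.element, "reverse")
        assert comp.terminator_repeat_count == 3

    def test_missing_component_flagged(self, element):
        # drop the linker and most of monomer 2
        partial = element.monomer1 + element.monomer2[60:] + element.terminator
        comp = decompose(partial, element, "forward")
        assert "linker" in comp.missing_components


class TestTandemCopies:
    def test_eland_two_copies_with_internal_evidence(self, panel, panel_calls):
        res = count_tandem_copies(
            panel_calls["eland"][0].inserted_sequence,
            panel.element,
            [panel.pali1, panel.pali2],
            "forward",
        )
        assert res.copy_number == 2
        assert res.internal_tsd_evidence is not None
        lo, hi = res.internal_tsd_evidence
        assert hi - lo >= 6
        assert res.flags == []

    def test_single_copy_species(self, panel, panel_calls):
        res = count_tandem_copies(
            panel_calls["goat"][0].inserted_sequence,
            panel.element,
            [panel.pali1, panel.pali2],
            "reverse",
        )
        assert res.copy_number == 1
        assert res.internal_tsd_evidence is None

    def test_two_copies_without_evidence_flagged(self, panel):
        """Ablation: deleting the internal truncated copy leaves two adjacent
        elements that look like one fused double-length element."""
        elem = panel.element.sequence
        fused = elem + elem
        res = count_tandem_copies(fused, panel.element, [panel.pali1, panel.pali2])
        assert res.copy_number == 2
        assert res.internal_tsd_evidence is None
        assert "bov_a4_like" in res.flags


class TestMonomerClassification:
    def test_canonical_assignment(self, element):
        comp = decompose(element.sequence, element, "forward")
        assignments = {a.segment: a.assigned for a in classify_monomers(comp, element)}
        assert assignments == {"monomer1": "monomer1", "monomer2": "monomer2"}

    def test_strand_invariant(self, element):
        rc = reverse_complement(element.sequence)
        comp = decompose(rc, element, "reverse")
        assignments = {a.segment: a.assigned for a in classify_monomers(comp, element)}
        assert assignments == {"monomer1": "monomer1", "monomer2": "monomer2"}

    def test_constructed_tie_is_ambiguous(self, element, rng):
        # flip half of the diagnostic sites in monomer 1 to the monomer-2 base
        seq = list(element.sequence)
        sites = element.diagnostic_sites
        for off, _b1, b2 in sites[: len(sites) // 2]:
            seq[off] = b2
        comp = decompose("".join(seq), element, "forward")
        (m1,) = [a for a in classify_monomers(comp, element) if a.segment == "monomer1"]
        assert m1.assigned == "ambiguous"
        assert m1.votes_monomer1 == m1.votes_monomer2


class TestVariants:
    def test_unmutated_insert_has_no_variants(self, element):
        assert call_variants(element.sequence, element, "forward") == []

    def test_goat_and_ibex_identical(self, panel, panel_calls):
        vg = call_variants(panel_calls["goat"][0].inserted_sequence, panel.element, "reverse")
        vi = call_variants(panel_calls["ibex"][0].inserted_sequence, panel.element, "reverse")
        assert vg == vi
        assert len(vg) == 6  # the configured clade-shared + caprine substitutions

    def test_planted_substitutions_recovered_exactly(self, element, rng):
        positions = sorted(rng.choice(250, size=10, replace=False))
        mutated = mutate(element.sequence, positions, rng)
        variants = call_variants(mutated, element, "forward")
        assert [v.position - 1 for v in variants] == list(positions)
        assert all(v.kind == "substitution" for v in variants)

    def test_strand_invariance(self, element, rng):
        positions = sorted(rng.choice(250, size=5, replace=False))
        mutated = mutate(element.sequence, positions, rng)
        fwd = call_variants(mutated, element, "forward")
        rev = call_variants(reverse_complement(mutated), element, "reverse")
        assert fwd == rev

    def test_sensitivity_at_two_percent_density(self, element):
        """>= 95% of planted substitutions recovered over 20 seeded
        replicates at 2% substitution density (no indels); exact at rate 0."""
        recovered = planted = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            k = max(1, int(round(0.02 * element.length)))
            positions = sorted(rng.choice(element.length, size=k, replace=False))
            mutated = mutate(element.sequence, positions, rng)
            variants = call_variants(mutated, element, "forward")
            got = {v.position - 1 for v in variants if v.kind == "substitution"}
            planted += len(positions)
            recovered += len(got & set(positions))
        assert recovered / planted >= 0.95

    def test_sharing_summary(self):
        from palinsert.annotate import VariantCall

        v = VariantCall(1, 25, "substitution", "T", "C")
        rows = summarize_variant_sharing({"goat": [v], "ibex": [v]})
        assert rows[0]["sharing"] == "shared"
        assert rows[0]["species"] == "goat,ibex"
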