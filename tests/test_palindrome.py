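import json
import math
from importlib import resources

import pytest

from palinsert.palindrome import (
    EnergyModel,
    Palindrome,
    compare_alleles,
    default_energy_model,
    find_palindromes,
    hairpin_dG,
    pairing_profile,
)
from palinsert.panel import build_palindrome_templates

from .oracles import brute_best_partition, brute_palindrome_spans, revcomp


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def templates():
    return build_palindrome_templates(seed=0)


class TestDetector:
    def test_perfect_four_mer(self):
        (p,) = find_palindromes("ACGT", min_total_length=4)
        assert (p.total_length, p.loop_length, p.mismatch_positions) == (4, 0, [])

    def test_wild_type_pali1_span(self, templates):
        pali1, _ = templates
        found = find_palindromes("TTATTCCT" + pali1.sequence + "TTATTCCT")
        assert max(p.total_length for p in found) == 18

    def test_equals_brute_force_on_random_sequences(self, rng):
        for _ in range(120):
            n = int(rng.integers(10, 61))
            seq = random_dna(rng, n)
            got = [(p.start, p.end) for p in find_palindromes(seq)]
            assert got == brute_palindrome_spans(seq)

    def test_partition_preference_matches_oracle(self, rng):
        for _ in range(60):
            seq = random_dna(rng, int(rng.integers(10, 45)))
            for p in find_palindromes(seq):
                n_mm = len(p.mismatch_positions) // 2
                assert brute_best_partition(seq, p.start, p.end) == (
                    n_mm,
                    p.loop_length,
                )

    def test_reverse_complement_invariance(self, rng):
        for _ in range(80):
            n = int(rng.integers(10, 61))
            seq = random_dna(rng, n)
            fwd = {(p.start, p.end) for p in find_palindromes(seq)}
            rev = {
                (n - p.end, n - p.start) for p in find_palindromes(revcomp(seq))
            }
            assert fwd == rev


class TestPairingProfile:
    def test_cow_allele_mismatch_at_position_14(self, templates):
        pali1, _ = templates
        cow = pali1.allele_sequence("cow")
        prof = pairing_profile(pali1, cow)
        assert prof.mismatch_positions == [14]

    def test_wild_type_has_no_mismatch(self, templates):
        pali1, _ = templates
        assert pairing_profile(pali1, pali1.sequence).mismatch_positions == []

    def test_detector_profile_reflects_under_revcomp(self, rng):
        for _ in range(40):
            n = int(rng.integers(12, 50))
            seq = random_dna(rng, n)
            for p in find_palindromes(seq):
                prof = pairing_profile(p, seq)
                rc = revcomp(seq)
                mirrored = [
                    q
                    for q in find_palindromes(rc)
                    if (n - q.end, n - q.start) == (p.start, p.end)
                ]
                assert mirrored, "reverse complement lost a span"
                prof_rc = pairing_profile(mirrored[0], rc)
                span = p.total_length
                reflected = sorted(span + 1 - m for m in prof_rc.mismatch_positions)
                assert reflected == prof.mismatch_positions


class TestHairpinEnergy:
    def test_poly_a_cannot_fold(self):
        assert hairpin_dG("A" * 20, [(i + 1, 20 - i) for i in range(4)]) == math.inf

    def test_hand_summed_twelve_mer(self):
        # GCGA TTTT TCGC: 4 bp stem, 4 nt loop; sum three stack steps and the
        # loop initiation straight from the packaged parameter file
        with resources.files("palinsert.data").joinpath("nn_dna_dG37.json").open() as fh:
            raw = json.load(fh)
        seq = "GCGATTTTTCGC"
        pairing = [(1, 12), (2, 11), (3, 10), (4, 9)]
        expected = (
            raw["stack"]["GC"]
            + raw["stack"]["CG"]
            + raw["stack"]["GA"]
            + raw["hairpin_loop"]["4"]
        )
        assert hairpin_dG(seq, pairing) == pytest.approx(expected)

    def test_crossing_pairs_rejected(self):
        with pytest.raises(ValueError, match="crossing"):
            hairpin_dG("ACGTACGT", [(1, 5), (2, 7)])

    def test_adding_wc_stack_never_raises_dG(self):
        """Extending a stem outward by one Watson-Crick pair adds a stack
        term; checked over all 16 dinucleotide steps."""
        model = default_energy_model()
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for outer in "ACGT":
            for inner in "ACGT":
                # hairpin: outer+inner arms around a TTTT loop
                core = inner + "TTTT" + comp[inner]
                base = hairpin_dG(core, [(1, 6)], model)
                ext = outer + core + comp[outer]
                extended = hairpin_dG(ext, [(1, 8), (2, 7)], model)
                assert extended <= base

    def test_cow_allele_less_stable_than_wild_type(self, templates):
        pali1, _ = templates
        dg_wt = hairpin_dG(pali1.sequence, pali1.paired_position_map)
        dg_cow = hairpin_dG(pali1.allele_sequence("cow"), pali1.paired_position_map)
        assert dg_cow > dg_wt


class TestCompareAlleles:
    def test_pali2_extension_is_stabilizing(self, templates):
        _, pali2 = templates
        cmp = compare_alleles(pali2, None, "eland")
        assert (cmp.span_a, cmp.span_b) == (14, 16)
        assert cmp.classification == "stabilizing"

    def test_pali1_cow_is_destabilizing(self, templates):
        pali1, _ = templates
        assert compare_alleles(pali1, None, "cow").classification == "destabilizing"

    def test_identical_alleles_neutral(self, templates):
        pali1, _ = templates
        cmp = compare_alleles(pali1, "cow", "cow")
        assert cmp.classification == "neutral"
        assert cmp.delta_g_a == cmp.delta_g_b

    def test_unknown_allele_rejected(self, templates):
        pali1, _ = templates
        with pytest.raises(KeyError):
            compare_alleles(pali1, None, "yak")


class TestEnergyModelValidation:
    def test_incomplete_stack_table_rejected(self):
        model = default_energy_model()
        stacks = dict(model.stack)
        stacks.pop("AA")
        with pytest.raises(ValueError, match="stack"):
            EnergyModel(
                stack=stacks,
                hairpin_loop=model.hairpin_loop,
                mismatch_penalty=1.0,
                bulge_penalty=3.5,
                extrapolation_per_nt=0.1,
            )
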