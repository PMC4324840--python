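import copy

import pytest

from palinsert.io_formats import reverse_complement
from palinsert.panel import (
    ConfigError,
    PALI1_TSD_COPY,
    SpeciesSpec,
    _apply_substitutions,
    build_consensus_element,
    build_palindrome_templates,
    build_panel,
    default_panel_config,
    plant_relic,
)


class TestConsensusElement:
    def test_architecture_lengths(self, element):
        assert element.length == 272
        assert len(element.monomer1) == 116
        assert len(element.linker) == 27
        assert len(element.monomer2) == 117
        assert element.terminator == "AGCAGCAGCAGC"

    def test_deterministic_per_seed(self):
        a = build_consensus_element(11)
        b = build_consensus_element(11)
        c = build_consensus_element(12)
        assert a.sequence == b.sequence
        assert c.sequence != a.sequence
        assert (c.length, len(c.monomer1)) == (a.length, len(a.monomer1))

    def test_diagnostic_sites_differ(self, element):
        assert len(element.diagnostic_sites) >= 5
        for off, b1, b2 in element.diagnostic_sites:
            assert element.monomer1[off] == b1
            assert element.monomer2[element._m2_offset(off)] == b2
            assert b1 != b2


class TestPalindromeTemplates:
    def test_pali1_constraints(self):
        pali1, _ = build_palindrome_templates(0)
        assert pali1.sequence.startswith("TCAGAAAGTGAT")
        assert len(pali1.sequence) == 18
        assert pali1.sequence[13] == "G"

    def test_eland_edit_list(self):
        _, pali2 = build_palindrome_templates(0)
        eland = pali2.allele_sequence("eland")
        assert len(eland) == len(pali2.sequence) - 4
        # single transversion beyond the deletion
        diffs = [
            k for k, (a, b) in enumerate(zip(eland, pali2.sequence)) if a != b
        ]
        assert diffs == [15]
        assert (pali2.sequence[15], eland[15]) == ("A", "C")


class TestDefaultPanel:
    def test_eight_of_fourteen_carry_elements(self, panel):
        assert len(panel.records) == 14
        carriers = [
            r.identifier
            for r in panel.records
            if any(a.feature_type == "element" for a in r.truth)
        ]
        assert len(carriers) == 8
        assert "eland" in carriers and "cow" not in carriers

    def test_cow_has_broken_pali1_and_no_element(self, panel):
        cow = panel.by_name("cow")
        p1 = next(
            a
            for a in cow.truth
            if a.feature_type == "palindrome" and a.attributes["name"] == "PALI1"
        )
        assert p1.attributes["allele"] == "cow"
        assert p1.attributes["intact"] == 0
        assert not any(a.feature_type == "element" for a in cow.truth)

    def test_buffalo_wild_type_and_empty(self, panel):
        buffalo = panel.by_name("buffalo")
        p1 = next(
            a
            for a in buffalo.truth
            if a.feature_type == "palindrome" and a.attributes["name"] == "PALI1"
        )
        assert p1.attributes["intact"] == 1
        assert not any(a.feature_type == "element" for a in buffalo.truth)

    def test_same_seed_is_byte_identical(self, panel):
        again = build_panel(default_panel_config(seed=1))
        for a, b in zip(panel.records, again.records):
            assert a.sequence == b.sequence
            assert a.truth == b.truth

    def test_length_accounting(self, panel):
        """Single insertion adds element length + duplicated copy length,
        and the truth table states both terms."""
        cow = panel.by_name("cow")
        for name in ("goat", "ibex", "sheep", "wildebeest", "gazelle"):
            rec = panel.by_name(name)
            (call,) = rec.metadata["expected_calls"]
            assert len(rec.sequence) - len(cow.sequence) == call["length"]
            assert call["length"] == call["element_length"] + call["tsd_copy_length"]
            assert call["element_length"] == 272

    def test_truth_relocates_by_string_search(self, panel):
        for rec in panel.records:
            for ann in rec.truth:
                sub = rec.sequence[ann.start : ann.end]
                assert rec.sequence.find(sub, ann.start) == ann.start

    def test_reverse_insertion_is_exact_reverse_complement(self, panel):
        """At background rate 0 the planted segment of a reverse-orientation
        species equals the reverse complement of the edited consensus."""
        goat_spec = next(s for s in panel.config.species if s.name == "goat")
        edited = _apply_substitutions(
            panel.element.sequence, [p for _c, p in goat_spec.element_substitutions]
        )
        rec = panel.by_name("goat")
        ann = next(a for a in rec.truth if a.feature_type == "element")
        assert rec.sequence[ann.start : ann.end] == reverse_complement(edited)

    def test_tsd_copy_planted_after_element(self, panel):
        rec = panel.by_name("goat")
        tsd = next(a for a in rec.truth if a.feature_type == "tsd_copy")
        assert rec.sequence[tsd.start : tsd.end] == PALI1_TSD_COPY


class TestRelic:
    def test_addax_terminator_interrupted(self, panel):
        rec = panel.by_name("addax")
        relic = next(a for a in rec.truth if a.feature_type == "relic")
        assert relic.attributes["polya_length"] == 12
        elem = next(a for a in rec.truth if a.feature_type == "element")
        # reverse strand: terminator sits reverse-complemented at the 5' side
        head = rec.sequence[elem.start : elem.start + 12]
        assert head != "GCT" * 4  # no longer a contiguous repeat run

    def test_non_addax_has_no_relic(self, panel):
        for rec in panel.records:
            if rec.identifier != "addax":
                assert not any(a.feature_type == "relic" for a in rec.truth)

    def test_short_polya_rejected(self, panel):
        rec = copy.deepcopy(panel.by_name("goat"))
        with pytest.raises(ConfigError, match="exceed 10"):
            plant_relic(rec, polya_length=10)

    def test_relic_needs_an_element(self, panel):
        rec = copy.deepcopy(panel.by_name("buffalo"))
        with pytest.raises(ConfigError, match="no element"):
            plant_relic(rec)


class TestConfigValidation:
    def test_empty_species_list(self):
        cfg = default_panel_config(1)
        cfg.species = []
        assert any("empty" in f for f in cfg.validate())

    def test_relic_without_insertion(self):
        cfg = default_panel_config(1)
        cfg.species.append(SpeciesSpec("yak", "Bovini", relic=True))
        assert any("relic" in f and f.startswith("error") for f in cfg.validate())

    def test_strict_polya_bound(self):
        cfg = default_panel_config(1)
        cfg.relic_polya_length = 10
        assert any("exceed 10" in f for f in cfg.validate())

    def test_mutation_spectrum_recorded(self, noisy_panel):
        n = sum(r.metadata["background_substitutions"] for r in noisy_panel.records)
        assert n > 0
        # protected features untouched: palindrome truths still relocate
        for rec in noisy_panel.records:
            for ann in rec.truth:
                if ann.feature_type == "palindrome":
                    assert rec.sequence[ann.start : ann.end].count("N") == 0
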