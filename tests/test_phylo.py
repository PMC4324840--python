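import pytest

from palinsert.io_formats import parse_newick
from palinsert.phylo import (
    CharacterMatrix,
    build_matrix,
    consistency_report,
    default_panel_tree,
    fitch_parsimony,
)

from .oracles import brute_fitch_min_changes

SPECIES = (
    "cow zebu buffalo eland goat ibex sheep wildebeest addax gazelle "
    "tibetan_antelope red_deer spotted_deer giraffe"
).split()
ANTILOPINAE = {
    "goat", "ibex", "sheep", "wildebeest", "addax", "gazelle", "tibetan_antelope"
}


@pytest.fixture()
def panel_matrix():
    presence = {
        sp: ({"IS1"} if sp in ANTILOPINAE else ({"IS2"} if sp == "eland" else set()))
        for sp in SPECIES
    }
    reports = {
        sp: {
            "pali1_mismatches": 1 if sp in {"cow", "zebu"} else 0,
            "pali2_max_span": 16 if sp == "eland" else 14,
        }
        for sp in SPECIES
    }
    return build_matrix(presence, reports, SPECIES)


def random_binary_newick(rng, n_leaves):
    """Random binary topology by sequential joining of subtrees."""
    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";", labels


class TestBuildMatrix:
    def test_default_panel_counts(self, panel_matrix):
        is1 = panel_matrix.characters["IS1_element"]
        is2 = panel_matrix.characters["IS2_element"]
        assert sum(v == 1 for v in is1.values()) == 7
        assert sum(v == 1 for v in is2.values()) == 1

    def test_buffalo_intact_but_empty(self, panel_matrix):
        assert panel_matrix.state("PALI1_intact", "buffalo") == 1
        assert panel_matrix.state("IS1_element", "buffalo") == 0

    def test_cow_pali1_broken(self, panel_matrix):
        assert panel_matrix.state("PALI1_intact", "cow") == 0

    def test_unassayed_species_marked(self):
        m = build_matrix({"a": {"IS1"}}, {"a": {"pali1_mismatches": 0, "pali2_max_span": 14}}, ["a", "b"])
        assert m.state("IS1_element", "b") == "?"
        assert m.state("PALI1_intact", "b") == "?"


class TestFitch:
    def test_constant_character_needs_no_change(self):
        tree = parse_newick("((a,b),(c,d));")
        m = CharacterMatrix(list("abcd"), {"x": {s: 1 for s in "abcd"}})
        assert fitch_parsimony(tree, m).per_character["x"].min_changes == 0

    def test_panel_characters_single_change(self, panel_matrix):
        """Every default-panel character maps with one change on the panel
        tree (single gain or single loss), matching the brute-force minimum."""
        tree = default_panel_tree()
        result = fitch_parsimony(tree, panel_matrix)
        for char, res in result.per_character.items():
            states = {
                sp: v for sp, v in panel_matrix.characters[char].items() if v != "?"
            }
            assert res.min_changes == brute_fitch_min_changes(tree, states)
            assert res.min_changes == 1
            assert not res.homoplasy

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 9))
            newick, labels = random_binary_newick(rng, n)
            tree = parse_newick(newick)
            states = {l: int(rng.integers(0, 2)) for l in labels}
            m = CharacterMatrix(labels, {"x": dict(states)})
            got = fitch_parsimony(tree, m).per_character["x"].min_changes
            assert got == brute_fitch_min_changes(tree, states)

    def test_invariant_under_leaf_permutation_and_rerooting(self):
        newick = "(((a,b),c),((d,e),f));"
        states = {"a": 1, "b": 1, "c": 0, "d": 1, "e": 0, "f": 0}
        m = CharacterMatrix(list("abcdef"), {"x": dict(states)})
        base = fitch_parsimony(parse_newick(newick), m).per_character["x"].min_changes
        m2 = CharacterMatrix(list("fedcba"), {"x": dict(states)})
        assert fitch_parsimony(parse_newick(newick), m2).per_character["x"].min_changes == base
        n_edges = len(list(parse_newick(newick).preorder_edge_iter()))
        for k in range(n_edges):
            tree = parse_newick(newick)
            edge = list(tree.preorder_edge_iter())[k]
            if edge.tail_node is None or edge.head_node.is_leaf():
                continue
            tree.reroot_at_edge(edge)
            got = fitch_parsimony(tree, m).per_character["x"].min_changes
            assert got == base

    def test_leaf_mismatch_names_offenders(self):
        tree = parse_newick("(a,b);")
        m = CharacterMatrix(["a", "b", "zz"], {"x": {"a": 0, "b": 1, "zz": 1}})
        with pytest.raises(ValueError, match="zz"):
            fitch_parsimony(tree, m)


class TestConsistency:
    def test_buffalo_flagged_capable_but_empty(self, panel_matrix):
        flags = consistency_report(panel_matrix)
        kinds = {(f.species, f.kind) for f in flags}
        assert ("buffalo", "capable_but_empty") in kinds

    def test_no_mechanistic_conflicts_in_default_panel(self, panel_matrix):
        assert all(
            f.kind != "mechanistic_conflict" for f in consistency_report(panel_matrix)
        )

    def test_disrupted_with_element_is_flagged(self):
        m = build_matrix(
            {"x": {"IS1"}},
            {"x": {"pali1_mismatches": 1, "pali2_max_span": 14}},
            ["x"],
        )
        (flag,) = consistency_report(m)
        assert flag.kind == "mechanistic_conflict"

    def test_empty_matrix_empty_report(self):
        assert consistency_report(CharacterMatrix([], {c: {} for c in ("PALI1_intact", "IS1_element")})) == []
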