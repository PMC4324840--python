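"""Presence/absence character mapping on a species tree.

Each insertion locus (and each palindrome state) is a binary character over
the species panel.  Fitch parsimony on a user tree gives the minimum number
of state changes per character; a presence/absence character needing more
than one change is flagged as homoplastic — a retroposon insertion is
assumed essentially unique, so such a marker is unreliable for phylogeny.
The module also cross-checks palindrome and element states for mechanistic
conflicts (an intact entrance palindrome with no element is insertion-
capable but empty; a disrupted palindrome with an element present
contradicts the entrance-site model).
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import dendropy

from .io_formats import parse_newick

CHARACTERS = ("IS1_element", "IS2_element", "PALI1_intact", "PALI2_extended")


def default_panel_tree() -> dendropy.Tree:
    """The packaged schematic tribe-level tree of the default 14-species panel."""
    text = resources.files("palinsert.data").joinpath("default_panel.nwk").read_text()
    return parse_newick(text, source="default_panel.nwk")


@dataclasses.dataclass
class CharacterMatrix:
    """Species x character states in {0, 1, '?'} ('?' = not assayed)."""

    species: list[str]
    characters: dict[str, dict[str, object]]  # char -> species -> 0|1|'?'

    def state(self, character: str, species: str):
        return self.characters[character][species]

    def to_rows(self) -> list[dict]:
        rows = []
        for sp in self.species:
            row = {"species": sp}
            for char in self.characters:
                row[char] = self.characters[char][sp]
            rows.append(row)
        return rows


def build_matrix(
    locus_presence: dict[str, set[str]],
    palindrome_reports: dict[str, dict],
    species_list: list[str],
) -> CharacterMatrix:
    """Assemble the character matrix from upstream stage outputs.

    ``locus_presence`` maps species to the set of locus labels at which an
    element was called; ``palindrome_reports`` maps species to
    ``{"pali1_mismatches": int, "pali2_max_span": int}``.  A species missing
    from either input gets '?' for the affected characters.  PALI1 is intact
    iff its pairing profile has zero mismatches; PALI2 is extended iff the
    maximal palindrome at its locus spans at least 16 nt.
    """
    characters: dict[str, dict[str, object]] = {c: {} for c in CHARACTERS}
    for sp in species_list:
        if sp in locus_presence:
            present = locus_presence[sp]
            characters["IS1_element"][sp] = int("IS1" in present)
            characters["IS2_element"][sp] = int("IS2" in present)
        else:
            characters["IS1_element"][sp] = "?"
            characters["IS2_element"][sp] = "?"
        rep = palindrome_reports.get(sp)
        if rep is None:
            characters["PALI1_intact"][sp] = "?"
            characters["PALI2_extended"][sp] = "?"
        else:
            characters["PALI1_intact"][sp] = int(rep["pali1_mismatches"] == 0)
            characters["PALI2_extended"][sp] = int(rep["pali2_max_span"] >= 16)
    return CharacterMatrix(list(species_list), characters)


@dataclasses.dataclass
class CharacterParsimony:
    character: str
    min_changes: int
    ancestral_states: list[tuple[str, int]]  # (sorted descendant leaves, state)
    homoplasy: bool


@dataclasses.dataclass
class ParsimonyResult:
    per_character: dict[str, CharacterParsimony]

    def homoplastic_characters(self) -> list[str]:
        return [c for c, r in self.per_character.items() if r.homoplasy]


def fitch_parsimony(tree: dendropy.Tree, matrix: CharacterMatrix) -> ParsimonyResult:
    """Fitch parsimony (unordered binary characters) on a rooted tree.

    Bottom-up pass: a node's state set is the intersection of its children's
    sets when non-empty, otherwise their union with one change counted.
    Leaves scored '?' are excluded from their character.  Top-down pass
    resolves one optimal ancestral assignment deterministically, preferring
    absence (state 0) at ties.  Polytomies are handled by folding children
    in left-to-right; the change count for binary trees equals the
    brute-force minimum over all ancestral labelings.
    """
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [sp for sp in matrix.species if sp not in leaf_labels]
    if missing:
        raise ValueError(f"species absent from the tree: {missing}")
    results = {}
    for char, states in matrix.characters.items():
        sets: dict = {}
        changes = 0
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                st = states.get(node.taxon.label, "?")
                sets[node] = None if st == "?" else frozenset({int(st)})
            else:
                child_sets = [sets[c] for c in node.child_nodes() if sets[c] is not None]
                if not child_sets:
                    sets[node] = None
                    continue
                acc = child_sets[0]
                for cs in child_sets[1:]:
                    inter = acc & cs
                    if inter:
                        acc = inter
                    else:
                        acc = acc | cs
                        changes += 1
                sets[node] = acc
        # top-down resolution, preferring state 0 at ties
        assignment: dict = {}
        for node in tree.preorder_node_iter():
            s = sets.get(node)
            if s is None:
                continue
            parent = node.parent_node
            if parent is not None and parent in assignment and assignment[parent] in s:
                assignment[node] = assignment[parent]
            else:
                assignment[node] = 0 if 0 in s else min(s)
        ancestral = []
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node not in assignment:
                continue
            leaves = sorted(
                l.taxon.label for l in node.leaf_iter() if sets.get(l) is not None
            )
            ancestral.append((",".join(leaves), assignment[node]))
        results[char] = CharacterParsimony(
            character=char,
            min_changes=changes,
            ancestral_states=ancestral,
            homoplasy=changes > 1,
        )
    return ParsimonyResult(results)


@dataclasses.dataclass
class ConsistencyFlag:
    species: str
    kind: str  # capable_but_empty | mechanistic_conflict
    detail: str


def consistency_report(matrix: CharacterMatrix) -> list[ConsistencyFlag]:
    """Palindrome/element conflicts per species.

    (a) an intact (or extended) entrance palindrome with no element at its
    locus: insertion-capable but empty; (b) a disrupted palindrome with an
    element present: conflicts with the entrance-site mechanism.
    """
    flags = []
    pal_char, el_char = "PALI1_intact", "IS1_element"
    for sp in matrix.species:
        pal = matrix.characters[pal_char].get(sp, "?")
        el = matrix.characters[el_char].get(sp, "?")
        if pal == "?" or el == "?":
            continue
        if pal == 1 and el == 0:
            flags.append(
                ConsistencyFlag(sp, "capable_but_empty", f"{pal_char}=1, {el_char}=0")
            )
        if pal == 0 and el == 1:
            flags.append(
                ConsistencyFlag(sp, "mechanistic_conflict", f"{pal_char}=0, {el_char}=1")
            )
    return flags
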