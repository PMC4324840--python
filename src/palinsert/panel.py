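"""Synthetic species panel: promoters with planted retroposon insertions.

The generator emulates a ruminant promoter panel in which a ~272 bp dimeric
retroposon (two homologous monomers joined by a 27 bp linker, terminated by
an [AGC]x4 repeat) entered a promoter at short palindromic loci: once, in
reverse orientation, at a locus ~500 bp upstream of the transcription start
site flanked by an 18 bp near-palindrome (PALI1), and — in one lineage — as
two sequential forward copies at a second palindromic locus (PALI2) 39 bp
downstream of the first.  Insertion leaves a duplicated, truncated copy of
the entrance palindrome on the 3' flank (a target-site-duplication footprint
of non-equal homologous recombination).

The panel ships with a per-species ground-truth table so that every
downstream stage (insertion calling, element annotation, palindrome and TSD
analysis, character mapping, motif classification) can be tested against
known answers.  Same seed and config give a byte-identical panel.

Positions are 0-based half-open internally.  The PALI1/PALI2 template
sequences are pinned constants built to satisfy every stated structural
constraint (span, target-site 12-mer, mutable 14th position, extendability);
only the element monomers and background sequence are drawn from the seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import AnnotationRecord, SequenceRecord, reverse_complement
from .palindrome import (
    AlleleEdit,
    PalindromeTemplate,
    find_palindromes,
    is_wc,
)

BASES = np.array(list("ACGT"))
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class GenerationError(RuntimeError):
    """The generator could not satisfy its structural constraints."""


class ConfigError(ValueError):
    """Inconsistent panel configuration."""


# ---------------------------------------------------------------------------
# Element model


@dataclasses.dataclass
class ElementModel:
    """The canonical retroposon architecture.

    Two homologous monomers (116 and 117 nt) joined by a 27 nt linker and
    terminated by ``terminator_copies`` repeats of ``terminator_unit``.
    ``diagnostic_sites`` are (offset within the monomer alignment, monomer-1
    base, monomer-2 base) triples at which the monomers always differ; the
    synthetic defaults are generator properties and are flagged as such in
    reports (real diagnostic sites are a user-supplied override).
    """

    monomer1: str
    linker: str
    monomer2: str
    terminator_unit: str = "AGC"
    terminator_copies: int = 4
    diagnostic_sites: list[tuple[int, str, str]] = dataclasses.field(default_factory=list)
    monomer2_insertion_offset: int | None = None
    max_other_divergence: float = 0.15

    def __post_init__(self) -> None:
        if len(self.monomer1) != 116 or len(self.monomer2) != 117:
            raise GenerationError("monomer lengths must be 116 and 117 nt")
        if len(self.linker) != 27:
            raise GenerationError("linker must be 27 nt")
        if len(self.diagnostic_sites) < 5:
            raise GenerationError("need at least 5 diagnostic sites")
        for off, b1, b2 in self.diagnostic_sites:
            if self.monomer1[off] != b1 or self.monomer2[self._m2_offset(off)] != b2:
                raise GenerationError(f"diagnostic site at monomer offset {off} is stale")
            if b1 == b2:
                raise GenerationError(f"diagnostic site at offset {off} does not differ")

    def _m2_offset(self, m1_offset: int) -> int:
        ins = self.monomer2_insertion_offset
        if ins is not None and m1_offset >= ins:
            return m1_offset + 1
        return m1_offset

    @property
    def terminator(self) -> str:
        return self.terminator_unit * self.terminator_copies

    @property
    def sequence(self) -> str:
        return self.monomer1 + self.linker + self.monomer2 + self.terminator

    @property
    def length(self) -> int:
        return len(self.sequence)

    def component_intervals(self) -> dict[str, tuple[int, int]]:
        """0-based half-open intervals of the components within the element."""
        a = len(self.monomer1)
        b = a + len(self.linker)
        c = b + len(self.monomer2)
        return {
            "monomer1": (0, a),
            "linker": (a, b),
            "monomer2": (b, c),
            "terminator": (c, c + len(self.terminator)),
        }


# synthetic motif words planted in the element (see motif_scan fixtures)
STAT_LIKE_WORD = "TTCCCGGAA"
NFKB_LIKE_WORD = "GGGACTTTCC"
SP1_LIKE_WORD = "GGGGCGGGG"
STAT_WORD_LINKER_OFFSET = 5  # within the 27 nt linker
NFKB_WORD_M2_OFFSET = 20  # within monomer 2

_DIAGNOSTIC_OFFSETS = (10, 30, 50, 75, 95, 110)
_M2_INSERTION_OFFSET = 58


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def build_consensus_element(seed: int) -> ElementModel:
    """Deterministic canonical element for a seed.

    Component lengths are architectural constants (116 + 27 + 117 + 3x4 =
    272 nt); monomer content varies with the seed under a few boundary
    constraints (the element starts with G; monomer 2 does not end in the
    terminator unit; the diagnostic sites always differ between monomers).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE1E]))
    for _attempt in range(200):
        m1 = "G" + _random_dna(rng, 115)
        linker = list(_random_dna(rng, 27))
        linker[STAT_WORD_LINKER_OFFSET : STAT_WORD_LINKER_OFFSET + len(STAT_LIKE_WORD)] = STAT_LIKE_WORD
        linker = "".join(linker)
        # monomer 2: homologous copy of monomer 1 with one extra nucleotide,
        # fixed differences at the diagnostic sites and a little extra drift
        m2 = list(m1)
        n_drift = 8
        drift_pool = [
            i
            for i in range(116)
            if i not in _DIAGNOSTIC_OFFSETS and not (0 <= i - NFKB_WORD_M2_OFFSET < len(NFKB_LIKE_WORD))
        ]
        drift_sites = rng.choice(drift_pool, size=n_drift, replace=False)
        for i in drift_sites:
            m2[i] = TRANSITION[m2[i]]
        diagnostics = []
        for off in _DIAGNOSTIC_OFFSETS:
            b1 = m1[off]
            b2 = TRANSITION[b1]
            m2[off] = b2
            diagnostics.append((off, b1, b2))
        m2.insert(_M2_INSERTION_OFFSET, str(_random_dna(rng, 1)))
        m2[NFKB_WORD_M2_OFFSET : NFKB_WORD_M2_OFFSET + len(NFKB_LIKE_WORD)] = NFKB_LIKE_WORD
        m2 = "".join(m2)
        if m2.endswith("AGC"):
            continue  # would extend the terminator run
        # the NFkB word must not clobber a diagnostic site
        stale = False
        for off, b1, b2 in diagnostics:
            o2 = off + 1 if off >= _M2_INSERTION_OFFSET else off
            if m2[o2] != b2:
                stale = True
        if stale:
            continue
        model = ElementModel(
            monomer1=m1,
            linker=linker,
            monomer2=m2,
            diagnostic_sites=diagnostics,
            monomer2_insertion_offset=_M2_INSERTION_OFFSET,
        )
        if model.length != 272:
            raise GenerationError("element length accounting broken")
        # planted motif words must occur exactly once; the entrance-site
        # 12-mer must not occur inside the element (keeps the target-site
        # search unambiguous)
        seq = model.sequence
        if _word_count_both_strands(seq, STAT_LIKE_WORD) != 1:
            continue
        if _word_count_both_strands(seq, NFKB_LIKE_WORD) != 1:
            continue
        if _word_count_both_strands(seq, SP1_LIKE_WORD) != 0:
            continue
        if _word_count_both_strands(seq, PALI1_SEQUENCE[6:]) != 0:
            continue
        return model
    raise GenerationError("could not build a consensus element under constraints")


# ---------------------------------------------------------------------------
# Palindrome templates

PALI1_SEQUENCE = "TCAGAAAGTGATTGCTGA"  # 18 nt; first 12 = entrance-site 12-mer
PALI1_TSD_12MER = "TCAGAAAGTGAT"
PALI1_WILD_MAP = [(1, 18), (2, 14), (3, 13), (5, 12)]
PALI2_SEQUENCE = "GCAGTCAATAGACTGAAACA"  # 20 nt; base 14 bp palindrome at 2..15
PALI2_WILD_MAP = [(2, 15), (3, 14), (4, 13), (5, 12), (6, 11)]
PALI2_ELAND_MAP = [(1, 16), (2, 15), (3, 14), (4, 13), (5, 12), (6, 11)]


def build_palindrome_templates(seed: int) -> tuple[PalindromeTemplate, PalindromeTemplate]:
    """The two entrance-site templates, PALI1 and PALI2.

    The sequences are fully pinned by structural constraints (the printed
    12-mer prefix, the mutable G at position 14, the 18/14/16 bp spans), so
    they do not vary with the seed; the seed argument is kept for interface
    uniformity with the other builders.  Construction re-validates every
    constraint and raises :class:`GenerationError` rather than relaxing one.
    """
    del seed
    pali1 = PalindromeTemplate(
        name="PALI1",
        sequence=PALI1_SEQUENCE,
        paired_position_map=list(PALI1_WILD_MAP),
        named_alleles={"cow": [AlleleEdit("sub", 14, "A")]},
    )
    pali2 = PalindromeTemplate(
        name="PALI2",
        sequence=PALI2_SEQUENCE,
        paired_position_map=list(PALI2_WILD_MAP),
        named_alleles={
            "eland": [AlleleEdit("sub", 16, "C")]
            + [AlleleEdit("del", p) for p in (17, 18, 19, 20)]
        },
        allele_pairing_maps={"eland": list(PALI2_ELAND_MAP)},
    )
    _validate_templates(pali1, pali2)
    return pali1, pali2


def _max_span(seq: str) -> int:
    found = find_palindromes(seq, min_total_length=4)
    return max((p.total_length for p in found), default=0)


def _validate_templates(pali1: PalindromeTemplate, pali2: PalindromeTemplate) -> None:
    if not pali1.sequence.startswith(PALI1_TSD_12MER):
        raise GenerationError("PALI1 must start with the entrance-site 12-mer")
    if pali1.sequence[13] != "G":
        raise GenerationError("PALI1 position 14 must be G in the wild type")
    if not any(14 in pair for pair in pali1.paired_position_map):
        raise GenerationError("PALI1 position 14 must be paired in the wild-type map")
    if _max_span(pali1.sequence) != 18:
        raise GenerationError("wild-type PALI1 must have maximal span 18")
    cow = pali1.allele_sequence("cow")
    broken = [
        (i, j)
        for i, j in pali1.paired_position_map
        if not is_wc(cow[i - 1], cow[j - 1])
    ]
    if len(broken) != 1 or 14 not in broken[0]:
        raise GenerationError("the cow allele must break exactly the pair at position 14")
    if _max_span(pali2.sequence) != 14:
        raise GenerationError("wild-type PALI2 must have maximal span 14")
    eland = pali2.allele_sequence("eland")
    if len(eland) != len(pali2.sequence) - 4:
        raise GenerationError("the eland allele must delete the last 4 nt")
    if _max_span(eland) != 16:
        raise GenerationError("the eland PALI2 allele must have maximal span 16")


# the duplicated, 5'-truncated entrance-palindrome copy left on the 3' flank
# of a first-locus insertion (last 12 nt of PALI1)
PALI1_TSD_COPY = PALI1_SEQUENCE[6:]
# both-side-truncated PALI2 copies flanking/separating the tandem elements
PALI2_TRUNCATED_COPY_SLICE = (2, 13)  # 0-based within the 16 nt eland allele


# ---------------------------------------------------------------------------
# Panel configuration


@dataclasses.dataclass
class SpeciesSpec:
    """Per-species insertion status, palindrome alleles and element edits."""

    name: str
    clade: str
    is1: str = "absent"  # absent | single_reverse | single_forward
    is2: str = "absent"  # absent | double_forward
    pali1_allele: str | None = None
    pali2_allele: str | None = None
    # (element copy index starting at 1, 1-based position in the consensus)
    element_substitutions: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    relic: bool = False

    def has_element(self) -> bool:
        return self.is1 != "absent" or self.is2 != "absent"


@dataclasses.dataclass
class PanelConfig:
    """Panel geometry, species table and generator parameters.

    Geometry default: a 1,588 nt promoter (1,088 nt non-coding region, a 450
    nt exon-1 portion, 50 nt margin) with the TSS at offset 1,538 and the
    first insertion locus 500 nt upstream of it; the second locus sits 39 nt
    downstream of the first.
    """

    species: list[SpeciesSpec]
    seed: int
    total_length: int = 1588
    tss_offset: int = 1538
    is1_upstream: int = 500
    locus_distance: int = 39
    mutation_rate: float = 0.0
    transition_fraction: float = 2 / 3
    relic_polya_length: int = 12
    relic_prefix_length: int = 8
    cpg_island: tuple[int, int] = (950, 1500)

    @property
    def is1(self) -> int:
        return self.tss_offset - self.is1_upstream

    @property
    def is2(self) -> int:
        return self.is1 + self.locus_distance

    def validate(self) -> list[str]:
        """Config findings; empty list means valid."""
        findings = []
        if not self.species:
            findings.append("error: species list is empty")
        if self.seed is None:
            findings.append("error: seed is mandatory")
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            findings.append("error: duplicate species names")
        pali1_len = len(PALI1_SEQUENCE)
        if not (pali1_len <= self.is1 and self.is2 + 4 <= self.tss_offset <= self.total_length):
            findings.append("error: insertion loci / TSS outside the promoter")
        if self.locus_distance < 20:
            findings.append("error: locus distance too small for the palindrome templates")
        if self.relic_polya_length <= 10:
            findings.append(
                "error: relic poly-A length must exceed 10 nt "
                f"(got {self.relic_polya_length})"
            )
        if self.relic_prefix_length < 6:
            findings.append("error: relic palindrome prefix must be at least 6 nt")
        if not (0.0 <= self.mutation_rate < 0.5):
            findings.append("error: mutation rate out of range")
        for sp in self.species:
            if sp.relic and not sp.has_element():
                findings.append(f"error: relic requested for insertion-free species {sp.name}")
            if sp.is1 not in {"absent", "single_reverse", "single_forward"}:
                findings.append(f"error: {sp.name}: unknown IS1 status {sp.is1!r}")
            if sp.is2 not in {"absent", "double_forward"}:
                findings.append(f"error: {sp.name}: unknown IS2 status {sp.is2!r}")
            if sp.element_substitutions and not sp.has_element():
                findings.append(f"error: element substitutions for insertion-free {sp.name}")
        if self.mutation_rate > 0.02:
            findings.append(f"warning: background mutation rate {self.mutation_rate} above 2%")
        return findings

    def ensure_valid(self) -> None:
        errors = [f for f in self.validate() if f.startswith("error")]
        if errors:
            raise ConfigError("; ".join(errors))


# element positions (1-based, consensus coordinates) used by the default panel
_ANTILOPINAE_SHARED = [25, 120, 160, 250]
_CAPRA_SHARED = [60, 210]
_SHEEP_WILDEBEEST_SHARED = [40, 200]
_GAZELLE_PRIVATE = [185, 190, 230]
_ELAND_COPY2_PRIVATE = [150, 175, 205]


def default_panel_config(seed: int, mutation_rate: float = 0.0) -> PanelConfig:
    """The default 14-species panel: 8 element-bearing species in 6 tribes,
    3 insertion-free bovids and 3 insertion-free outgroup species."""

    def rev(subs: list[int]) -> list[tuple[int, int]]:
        return [(1, p) for p in subs]

    species = [
        SpeciesSpec("cow", "Bovini", pali1_allele="cow"),
        SpeciesSpec("zebu", "Bovini", pali1_allele="cow"),
        SpeciesSpec("buffalo", "Bovini"),
        SpeciesSpec(
            "eland",
            "Tragelaphini",
            is2="double_forward",
            pali2_allele="eland",
            element_substitutions=[(2, p) for p in _ELAND_COPY2_PRIVATE],
        ),
        SpeciesSpec(
            "goat", "Caprini", is1="single_reverse",
            element_substitutions=rev(_ANTILOPINAE_SHARED + _CAPRA_SHARED),
        ),
        SpeciesSpec(
            "ibex", "Caprini", is1="single_reverse",
            element_substitutions=rev(_ANTILOPINAE_SHARED + _CAPRA_SHARED),
        ),
        SpeciesSpec(
            "sheep", "Caprini", is1="single_reverse",
            element_substitutions=rev(_ANTILOPINAE_SHARED + _SHEEP_WILDEBEEST_SHARED),
        ),
        SpeciesSpec(
            "wildebeest", "Alcelaphini", is1="single_reverse",
            element_substitutions=rev(_ANTILOPINAE_SHARED + _SHEEP_WILDEBEEST_SHARED),
        ),
        SpeciesSpec(
            "addax", "Hippotragini", is1="single_reverse",
            element_substitutions=rev(_ANTILOPINAE_SHARED),
            relic=True,
        ),
        SpeciesSpec(
            "gazelle", "Antilopini", is1="single_reverse",
            element_substitutions=rev(_ANTILOPINAE_SHARED + [60] + _GAZELLE_PRIVATE),
        ),
        SpeciesSpec(
            "tibetan_antelope", "Pantholopini", is1="single_reverse",
            element_substitutions=rev(_ANTILOPINAE_SHARED),
        ),
        SpeciesSpec("red_deer", "Cervidae"),
        SpeciesSpec("spotted_deer", "Cervidae"),
        SpeciesSpec("giraffe", "Giraffidae"),
    ]
    return PanelConfig(species=species, seed=int(seed), mutation_rate=mutation_rate)


# ---------------------------------------------------------------------------
# Promoter records


@dataclasses.dataclass
class PromoterRecord:
    """A species' promoter with its TSS anchor and planted ground truth."""

    record: SequenceRecord
    tss_position: int
    truth: list[AnnotationRecord] = dataclasses.field(default_factory=list)
    clade: str = ""
    metadata: dict = dataclasses.field(default_factory=dict)

    @property
    def identifier(self) -> str:
        return self.record.identifier

    @property
    def sequence(self) -> str:
        return self.record.sequence


def _apply_substitutions(element_seq: str, positions: list[int]) -> str:
    """Apply deterministic transition substitutions at 1-based positions."""
    bases = list(element_seq)
    for pos in positions:
        if not (1 <= pos <= len(bases)):
            raise ConfigError(f"element substitution position {pos} out of range")
        bases[pos - 1] = TRANSITION[bases[pos - 1]]
    return "".join(bases)


def _species_element(
    model: ElementModel, spec: SpeciesSpec, copy_index: int
) -> str:
    subs = [p for c, p in spec.element_substitutions if c == copy_index]
    return _apply_substitutions(model.sequence, subs)


@dataclasses.dataclass
class Panel:
    """The generated panel: records, the element model and the templates."""

    config: PanelConfig
    element: ElementModel
    pali1: PalindromeTemplate
    pali2: PalindromeTemplate
    records: list[PromoterRecord]

    def by_name(self, name: str) -> PromoterRecord:
        for rec in self.records:
            if rec.identifier == name:
                return rec
        raise KeyError(name)

    def truth_table(self) -> list[dict]:
        rows = []
        for rec in self.records:
            for ann in rec.truth:
                row = {
                    "species": rec.identifier,
                    "feature": ann.feature_type,
                    "start": ann.start,
                    "end": ann.end,
                    "strand": ann.strand,
                }
                row.update({k: str(v) for k, v in ann.attributes.items()})
                rows.append(row)
        return rows


def _word_positions(seq: str, word: str) -> list[int]:
    out = []
    start = 0
    while True:
        k = seq.find(word, start)
        if k < 0:
            return out
        out.append(k)
        start = k + 1


def _word_count_both_strands(seq: str, word: str) -> int:
    return len(_word_positions(seq, word)) + len(_word_positions(seq, reverse_complement(word)))


def build_panel(config: PanelConfig) -> Panel:
    """Generate the panel: one promoter per species plus ground truth.

    The shared backbone (the insertion-free promoter frame) is drawn from the
    seed and rejection-validated: the planted palindromes must be the locally
    maximal near-palindromes at their loci at exactly the designed spans, the
    planted motif words must occur nowhere else, and the bases adjacent to
    the insertion points must not allow the called insertion to slide past
    its 3'-normalized anchor.  Validation failures redraw the random context
    (never the pinned templates); an unsatisfiable configuration raises
    :class:`GenerationError`.
    """
    config.ensure_valid()
    pali1, pali2 = build_palindrome_templates(config.seed)
    element = build_consensus_element(config.seed)
    backbone, geometry = _build_backbone(config, element, pali1, pali2)
    records = []
    for idx, spec in enumerate(config.species):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 3, idx])
        )
        rec = _assemble_species(config, spec, element, pali1, pali2, backbone, geometry)
        _apply_background_mutations(config, rec, rng)
        records.append(rec)
    return Panel(config=config, element=element, pali1=pali1, pali2=pali2, records=records)


@dataclasses.dataclass
class _Geometry:
    p1_start: int
    p1_end: int  # == IS1
    w_start: int
    w_end: int
    is2: int
    sp1_position: int


def _longest_common_substring(a: str, b: str) -> str:
    best = ""
    subs = {a[i:j] for i in range(len(a)) for j in range(i + 1, len(a) + 1)}
    for i in range(len(b)):
        for j in range(i + len(best) + 1, len(b) + 1):
            if b[i:j] in subs:
                if j - i > len(best):
                    best = b[i:j]
            else:
                break
    return best


def _max_span_overlapping(seq: str, win_start: int, win_end: int, lo: int, hi: int) -> tuple[int, tuple[int, int] | None]:
    """Maximal palindrome span overlapping [lo, hi) within a scan window."""
    found = find_palindromes(seq[win_start:win_end])
    best = 0
    best_iv = None
    for p in found:
        s, e = p.start + win_start, p.end + win_start
        if s < hi and lo < e and p.total_length > best:
            best = p.total_length
            best_iv = (s, e)
    return best, best_iv


def _build_backbone(
    config: PanelConfig,
    element: ElementModel,
    pali1: PalindromeTemplate,
    pali2: PalindromeTemplate,
) -> tuple[str, _Geometry]:
    is1 = config.is1
    p1_start = is1 - pali1.length
    w_start = config.is2 - 16  # the entrance point splits the template at 16
    w_end = w_start + pali2.length
    if w_start < is1:
        raise ConfigError("locus distance too small: palindrome templates overlap")
    sp1_position = config.cpg_island[0] + 50
    sp1_end = sp1_position + len(SP1_LIKE_WORD)
    if not (0 <= sp1_position and sp1_end <= config.total_length):
        raise ConfigError("CpG island interval does not fit the promoter geometry")
    if not (sp1_end <= p1_start or sp1_position >= w_end):
        raise ConfigError("background motif word would overlap a planted palindrome")
    eland_seq = pali2.allele_sequence("eland")
    trunc = eland_seq[PALI2_TRUNCATED_COPY_SLICE[0] : PALI2_TRUNCATED_COPY_SLICE[1]]
    elem_rc = reverse_complement(element.sequence)
    for attempt in range(300):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 2, attempt])
        )
        upstream = _random_dna(rng, p1_start)
        spacer = _random_dna(rng, w_start - is1)
        downstream = _random_dna(rng, config.total_length - w_end)
        backbone = upstream + pali1.sequence + spacer + pali2.sequence + downstream
        backbone = backbone[:sp1_position] + SP1_LIKE_WORD + backbone[sp1_end:]
        if len(backbone) != config.total_length:
            raise GenerationError("backbone length accounting broken")
        if spacer[0] == "G":  # would let the called insertion slide right
            continue
        if spacer[-1] in "CG":  # could extend the second palindrome leftward
            continue
        if upstream[-1] == "C":  # could pair with the reverse element's first G
            continue
        # planted palindromes must be the locally maximal ones at their loci
        span, iv = _max_span_overlapping(
            backbone, max(0, p1_start - 40), is1 + 40, p1_start, is1
        )
        if span != 18 or iv != (p1_start, is1):
            continue
        span, iv = _max_span_overlapping(
            backbone, is1, w_end + 40, w_start, w_end
        )
        if span != 14 or iv != (w_start + 1, w_start + 15):
            continue
        # planted motif words occur exactly where planted, nowhere else
        if _word_count_both_strands(backbone, STAT_LIKE_WORD) != 0:
            continue
        if _word_count_both_strands(backbone, NFKB_LIKE_WORD) != 0:
            continue
        if _word_count_both_strands(backbone, SP1_LIKE_WORD) != 1:
            continue
        # the duplicated target copy must be the unique longest repeat
        # shared by the two 30 nt windows flanking a first-locus insertion
        up_win = backbone[is1 - 30 : is1]
        down_win = (PALI1_TSD_COPY + backbone[is1:])[:30]
        lcs = _longest_common_substring(up_win, down_win)
        if lcs != PALI1_TSD_COPY:
            continue
        # probe assemblies: the planted loci must stay locally maximal with
        # the element in place
        probe1 = backbone[:is1] + elem_rc + PALI1_TSD_COPY + backbone[is1:]
        span, iv = _max_span_overlapping(
            probe1, max(0, p1_start - 40), p1_start + 58, p1_start, is1
        )
        if span != 18 or iv != (p1_start, is1):
            continue
        eprobe = (
            backbone[:w_start]
            + eland_seq
            + element.sequence
            + trunc
            + element.sequence
            + trunc
            + backbone[w_start + 16 :]
        )
        span, iv = _max_span_overlapping(
            eprobe, w_start - 40, w_start + 56, w_start, w_start + 16
        )
        if span != 16 or iv != (w_start, w_start + 16):
            continue
        # the truncated second-locus copy must be the unique longest repeat
        # shared by the element flanks in the tandem insertion
        is2 = config.is2
        eflank5 = eprobe[is2 - 30 : is2]
        eflank3 = (trunc + backbone[w_start + 16 :])[:30]
        if _longest_common_substring(eflank5, eflank3) != trunc:
            continue
        geometry = _Geometry(
            p1_start=p1_start,
            p1_end=is1,
            w_start=w_start,
            w_end=w_end,
            is2=config.is2,
            sp1_position=sp1_position,
        )
        return backbone, geometry
    raise GenerationError(
        "could not draw a backbone satisfying the locus constraints; "
        "try a different seed or geometry"
    )


def _element_truth_extras(
    name: str,
    element: ElementModel,
    e_at: int,
    strand: str,
    copy_index: int,
    truth: list[AnnotationRecord],
) -> None:
    """Motif-word and diagnostic-site truth rows for one planted element copy."""
    length = element.length

    def to_promoter(lo: int, hi: int) -> tuple[int, int]:
        if strand == "+":
            return e_at + lo, e_at + hi
        return e_at + length - hi, e_at + length - lo

    linker_start = len(element.monomer1)
    m2_start = linker_start + len(element.linker)
    words = [
        ("stat_like", STAT_LIKE_WORD, linker_start + STAT_WORD_LINKER_OFFSET),
        ("nfkb_like", NFKB_LIKE_WORD, m2_start + NFKB_WORD_M2_OFFSET),
    ]
    for label, word, epos in words:
        lo, hi = to_promoter(epos, epos + len(word))
        truth.append(
            AnnotationRecord(
                name, lo, hi, strand, "motif_word",
                {"motif": label, "copy_index": copy_index, "inside_element": True},
            )
        )
    for off, b1, b2 in element.diagnostic_sites:
        for monomer, epos, base in (
            (1, off, b1),
            (2, m2_start + element._m2_offset(off), b2),
        ):
            lo, hi = to_promoter(epos, epos + 1)
            truth.append(
                AnnotationRecord(
                    name, lo, hi, strand, "diagnostic_site",
                    {
                        "monomer": monomer,
                        "offset": off,
                        "base": base,
                        "copy_index": copy_index,
                        "synthetic_default": True,
                    },
                )
            )


def _assemble_species(
    config: PanelConfig,
    spec: SpeciesSpec,
    element: ElementModel,
    pali1: PalindromeTemplate,
    pali2: PalindromeTemplate,
    backbone: str,
    geom: _Geometry,
) -> PromoterRecord:
    truth: list[AnnotationRecord] = []
    expected_calls: list[dict] = []
    name = spec.name
    parts: list[str] = []
    pos = 0  # cursor in the assembled sequence

    def emit(segment: str) -> int:
        nonlocal pos
        parts.append(segment)
        start = pos
        pos += len(segment)
        return start

    # upstream region
    emit(backbone[: geom.p1_start])
    # first entrance palindrome (species allele)
    p1_seq = pali1.allele_sequence(spec.pali1_allele)
    if len(p1_seq) != pali1.length:
        raise ConfigError(f"{name}: PALI1 alleles must preserve length")
    p1_at = emit(p1_seq)
    intact = all(is_wc(p1_seq[i - 1], p1_seq[j - 1]) for i, j in pali1.paired_position_map)
    truth.append(
        AnnotationRecord(
            name, p1_at, p1_at + pali1.length, "+", "palindrome",
            {
                "name": "PALI1",
                "allele": spec.pali1_allele or "wild_type",
                "intact": int(intact),
            },
        )
    )
    # first insertion locus
    if spec.is1 != "absent":
        elem_seq = _species_element(element, spec, 1)
        if spec.is1 == "single_reverse":
            ins_elem = reverse_complement(elem_seq)
            strand = "-"
        else:
            ins_elem = elem_seq
            strand = "+"
        e_at = emit(ins_elem)
        truth.append(
            AnnotationRecord(
                name, e_at, e_at + len(ins_elem), strand, "element",
                {
                    "locus": "IS1",
                    "copy_index": 1,
                    "orientation": "reverse" if strand == "-" else "forward",
                    "n_substitutions": sum(1 for c, _p in spec.element_substitutions if c == 1),
                },
            )
        )
        _element_truth_extras(name, element, e_at, strand, 1, truth)
        t_at = emit(PALI1_TSD_COPY)
        truth.append(
            AnnotationRecord(
                name, t_at, t_at + len(PALI1_TSD_COPY), "+", "tsd_copy",
                {
                    "locus": "IS1",
                    "copy_of": "PALI1",
                    "tsd_length": len(PALI1_TSD_COPY),
                    "truncated_5prime": True,
                    "truncated_3prime": False,
                },
            )
        )
        expected_calls.append(
            {
                "locus": "IS1",
                "ref_position": geom.p1_end,
                "length": len(ins_elem) + len(PALI1_TSD_COPY),
                "element_length": len(ins_elem),
                "tsd_copy_length": len(PALI1_TSD_COPY),
            }
        )
    # inter-locus spacer
    emit(backbone[geom.p1_end : geom.w_start])
    # second entrance palindrome and (optionally) the tandem insertion
    if spec.is2 == "double_forward":
        if spec.pali2_allele != "eland":
            raise ConfigError(f"{name}: double insertion requires the extended PALI2 allele")
        e_seq = pali2.allele_sequence("eland")
        trunc = e_seq[PALI2_TRUNCATED_COPY_SLICE[0] : PALI2_TRUNCATED_COPY_SLICE[1]]
        w_at = emit(e_seq)
        truth.append(
            AnnotationRecord(
                name, w_at, w_at + len(e_seq), "+", "palindrome",
                {"name": "PALI2", "allele": "eland", "span": 16},
            )
        )
        ins_len = 0
        for copy_index in (1, 2):
            elem_seq = _species_element(element, spec, copy_index)
            c_at = emit(elem_seq)
            ins_len += len(elem_seq)
            truth.append(
                AnnotationRecord(
                    name, c_at, c_at + len(elem_seq), "+", "element",
                    {
                        "locus": "IS2",
                        "copy_index": copy_index,
                        "orientation": "forward",
                        "n_substitutions": sum(
                            1 for c, _p in spec.element_substitutions if c == copy_index
                        ),
                    },
                )
            )
            _element_truth_extras(name, element, c_at, "+", copy_index, truth)
            t_at = emit(trunc)
            ins_len += len(trunc)
            truth.append(
                AnnotationRecord(
                    name, t_at, t_at + len(trunc), "+", "tsd_copy",
                    {
                        "locus": "IS2",
                        "copy_of": "PALI2",
                        "tsd_length": len(trunc),
                        "truncated_5prime": True,
                        "truncated_3prime": True,
                        "internal": copy_index == 1,
                    },
                )
            )
        expected_calls.append(
            {
                "locus": "IS2",
                "ref_position": geom.is2,
                "length": ins_len,
                "element_length": 2 * element.length,
                "tsd_copy_length": len(trunc),
            }
        )
        emit(backbone[geom.w_start + 16 :])
    else:
        w_seq = pali2.allele_sequence(spec.pali2_allele)
        w_at = emit(w_seq)
        truth.append(
            AnnotationRecord(
                name, w_at, w_at + len(w_seq), "+", "palindrome",
                {
                    "name": "PALI2",
                    "allele": spec.pali2_allele or "wild_type",
                    "span": 16 if spec.pali2_allele == "eland" else 14,
                },
            )
        )
        emit(backbone[geom.w_end :])
    sequence = "".join(parts)
    inserted = len(sequence) - config.total_length
    tss = config.tss_offset + inserted  # every planted locus is upstream of the TSS
    sp1_at = (
        geom.sp1_position
        if geom.sp1_position < geom.p1_start
        else geom.sp1_position + inserted
    )
    truth.append(
        AnnotationRecord(
            name, sp1_at, sp1_at + len(SP1_LIKE_WORD), "+", "motif_word",
            {"motif": "sp1_like", "inside_element": False},
        )
    )
    truth.sort(key=lambda a: (a.start, a.end))
    record = PromoterRecord(
        record=SequenceRecord(name, sequence, f"synthetic promoter ({spec.clade})"),
        tss_position=tss,
        truth=truth,
        clade=spec.clade,
        metadata={
            "species": name,
            "clade": spec.clade,
            "is1": spec.is1,
            "is2": spec.is2,
            "expected_calls": expected_calls,
            "inserted_length": inserted,
            "relic": False,
        },
    )
    if spec.relic:
        plant_relic(
            record,
            polya_length=config.relic_polya_length,
            prefix_length=config.relic_prefix_length,
        )
    return record


_PROTECTED_FEATURES = {"palindrome", "tsd_copy", "relic", "motif_word", "diagnostic_site"}


def _apply_background_mutations(
    config: PanelConfig, record: PromoterRecord, rng: np.random.Generator
) -> None:
    """Background point mutations at the configured rate.

    Planted palindromes, target-site copies, relics, motif words and
    diagnostic sites are never touched (keeps planted truth interpretable);
    everything else, including element bodies, is fair game.  Substitutions
    only — promoter lengths stay fixed.
    """
    rate = config.mutation_rate
    if rate <= 0:
        record.metadata["background_substitutions"] = 0
        return
    seq = record.record.sequence
    protected = np.zeros(len(seq), dtype=bool)
    for ann in record.truth:
        if ann.feature_type in _PROTECTED_FEATURES:
            protected[ann.start : ann.end] = True
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    bases = list(seq)
    n_applied = 0
    for pos in hits:
        if protected[pos]:
            continue
        ref = bases[pos]
        if ref not in TRANSITION:
            continue
        if rng.random() < config.transition_fraction:
            bases[pos] = TRANSITION[ref]
        else:
            choices = [b for b in "ACGT" if b != ref and b != TRANSITION[ref]]
            bases[pos] = choices[int(rng.integers(0, 2))]
        n_applied += 1
    record.record.sequence = "".join(bases)
    record.metadata["background_substitutions"] = n_applied


def plant_relic(
    record: PromoterRecord,
    element_interval: tuple[int, int] | None = None,
    polya_length: int = 12,
    prefix_length: int = 8,
) -> PromoterRecord:
    """Plant a secondary-insertion relic inside an element's terminator.

    The relic — a poly-A run (> 10 nt) immediately followed by a prefix of
    the first entrance palindrome — is inserted between the third and fourth
    terminator triplets of the element, leaving the terminator no longer a
    contiguous [AGC]x4 run.  Truth annotations, expected calls and the TSS
    anchor are shifted accordingly.  The record is modified in place and
    returned.
    """
    if polya_length <= 10:
        raise ConfigError(f"relic poly-A length must exceed 10 nt (got {polya_length})")
    if prefix_length < 6:
        raise ConfigError("relic palindrome prefix must be at least 6 nt")
    elements = [a for a in record.truth if a.feature_type == "element"]
    if element_interval is not None:
        elements = [a for a in elements if (a.start, a.end) == tuple(element_interval)]
    if not elements:
        raise ConfigError(f"{record.identifier}: no element to host a relic")
    host = elements[0]
    relic_elem = "A" * polya_length + PALI1_SEQUENCE[:prefix_length]
    if host.strand == "-":
        # the terminator sits reverse-complemented at the element's 5' side in
        # promoter coordinates; element-space "between triplets 3 and 4" is 3 nt
        # in from the start
        point = host.start + 3
        relic_seq = reverse_complement(relic_elem)
        strand = "-"
    else:
        point = host.end - 3
        relic_seq = relic_elem
        strand = "+"
    n = len(relic_seq)
    seq = record.record.sequence
    record.record.sequence = seq[:point] + relic_seq + seq[point:]
    for ann in record.truth:
        if ann.start >= point:
            ann.start += n
            ann.end += n
        elif ann.end > point:
            ann.end += n
    record.truth.append(
        AnnotationRecord(
            record.identifier, point, point + n, strand, "relic",
            {
                "polya_length": polya_length,
                "prefix_length": prefix_length,
                "host_locus": host.attributes.get("locus", "?"),
            },
        )
    )
    record.truth.sort(key=lambda a: (a.start, a.end))
    if record.tss_position >= point:
        record.tss_position += n
    for call in record.metadata.get("expected_calls", []):
        call["length"] += n
        call["element_length"] += n
    record.metadata["inserted_length"] = record.metadata.get("inserted_length", 0) + n
    record.metadata["relic"] = True
    return record
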