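"""Decomposition of called insertions into retroposon components.

Given an inserted sequence and the canonical element model, this module
infers the element's orientation, locates monomers/linker/terminator,
distinguishes two tandem copies from a single fused element by internal
target-site evidence, classifies monomer segments by diagnostic sites, and
calls variants against the consensus on consensus coordinates.
"""

from __future__ import annotations

import dataclasses

from .align import DEFAULT_SCORING, PairwiseAlignment, Scoring, global_align, local_align
from .io_formats import reverse_complement
from .palindrome import PalindromeTemplate
from .panel import ElementModel

ORIENTATION_FLOOR_FRACTION = 0.4
COPY_SCORE_FLOOR_FRACTION = 0.4
MIN_INTERNAL_TSD_MATCH = 6


@dataclasses.dataclass
class OrientationResult:
    orientation: str  # forward | reverse | unrecognized
    forward_score: float
    reverse_score: float

    @property
    def margin(self) -> float:
        return abs(self.forward_score - self.reverse_score)


def orient_element(
    insert_seq: str,
    element: ElementModel,
    scoring: Scoring = DEFAULT_SCORING,
    floor_fraction: float = ORIENTATION_FLOOR_FRACTION,
) -> OrientationResult:
    """Orientation of an insertion by local alignment against the consensus.

    Both strands are scored; the argmax wins (forward on an exact tie).  If
    both scores fall below ``floor_fraction`` of the maximum attainable local
    score the insertion is reported as not a recognizable element — an
    outcome, not an error.
    """
    if len(insert_seq) < 100:
        raise ValueError("orientation needs at least 100 nt of inserted sequence")
    consensus = element.sequence
    fwd = local_align(consensus, insert_seq, scoring).score
    rev = local_align(reverse_complement(consensus), insert_seq, scoring).score
    floor = floor_fraction * scoring.match * min(len(insert_seq), len(consensus))
    if fwd < floor and rev < floor:
        orientation = "unrecognized"
    elif fwd >= rev:
        orientation = "forward"
    else:
        orientation = "reverse"
    return OrientationResult(orientation, fwd, rev)


@dataclasses.dataclass
class ComponentAnnotation:
    """Component intervals of one element copy, in oriented-insert coordinates.

    ``oriented_sequence`` is the insert after reverse-complementing when the
    element is reverse-oriented, so components always appear in consensus
    order.  Intervals are 0-based half-open; flanking target-site remnants
    fall outside the component intervals.
    """

    orientation: str
    oriented_sequence: str
    intervals: dict[str, tuple[int, int]]
    terminator_repeat_count: int
    aligned_fraction: dict[str, float]
    missing_components: list[str]
    alignment: PairwiseAlignment
    copy_number: int = 1
    internal_tsd_evidence: tuple[int, int] | None = None

    @property
    def is_partial(self) -> bool:
        return bool(self.missing_components)


def _oriented(insert_seq: str, orientation: str) -> str:
    if orientation == "reverse":
        return reverse_complement(insert_seq)
    return insert_seq


def decompose(
    insert_seq: str,
    element: ElementModel,
    orientation: str,
    scoring: Scoring = DEFAULT_SCORING,
) -> ComponentAnnotation:
    """Locate monomers, linker and terminator within an insertion.

    The oriented insert is globally aligned to the consensus; component
    boundaries are mapped through the alignment.  The terminator repeat
    count is the maximal run of exact terminator units from the terminator's
    aligned start, so a relic interrupting the run is excluded.  A component
    with less than half of its consensus positions aligned is flagged
    missing (partial-element outcome).
    """
    if orientation not in {"forward", "reverse"}:
        raise ValueError(f"orientation must be determined first (got {orientation!r})")
    oriented = _oriented(insert_seq, orientation)
    aln = global_align(element.sequence, oriented, scoring, "consensus", "insert")
    coord = aln.coordinate_map()
    intervals: dict[str, tuple[int, int]] = {}
    aligned_fraction: dict[str, float] = {}
    missing: list[str] = []
    for name, (lo, hi) in element.component_intervals().items():
        cols = [(r, q) for r, q in coord if lo <= r < hi]
        if not cols:
            intervals[name] = (0, 0)
            aligned_fraction[name] = 0.0
            missing.append(name)
            continue
        q_lo = cols[0][1]
        q_hi = cols[-1][1] + 1
        intervals[name] = (q_lo, q_hi)
        frac = len(cols) / (hi - lo)
        aligned_fraction[name] = frac
        if frac < 0.5:
            missing.append(name)
    # terminator repeats: maximal exact run of the unit from the terminator start
    unit = element.terminator_unit
    t_lo, _t_hi = intervals.get("terminator", (0, 0))
    count = 0
    if "terminator" not in missing:
        k = t_lo
        while oriented[k : k + len(unit)] == unit:
            count += 1
            k += len(unit)
        intervals["terminator"] = (t_lo, t_lo + count * len(unit))
    return ComponentAnnotation(
        orientation=orientation,
        oriented_sequence=oriented,
        intervals=intervals,
        terminator_repeat_count=count,
        aligned_fraction=aligned_fraction,
        missing_components=missing,
        alignment=aln,
    )


@dataclasses.dataclass
class TandemResult:
    copy_number: int
    copy_intervals: list[tuple[int, int]]  # oriented-insert coordinates
    internal_tsd_evidence: tuple[int, int] | None
    flags: list[str]


def _longest_common_substring_position(a: str, b: str) -> tuple[int, int, int]:
    """(length, start_in_a, start_in_b) of the longest exact common substring."""
    best = (0, 0, 0)
    # a and b are short windows; quadratic is fine
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k] and a[i + k] != "N":
                k += 1
            if k > best[0]:
                best = (k, i, j)
    return best


def count_tandem_copies(
    insert_seq: str,
    element: ElementModel,
    tsd_templates: list[PalindromeTemplate] | None = None,
    orientation: str = "forward",
    scoring: Scoring = DEFAULT_SCORING,
    floor_fraction: float = COPY_SCORE_FLOOR_FRACTION,
) -> TandemResult:
    """Count element copies by iterated best local alignment with masking.

    Each round aligns the (oriented) insert against the consensus and masks
    the hit; rounds stop when the best score drops below ``floor_fraction``
    of a perfect single-copy score.  With two copies, the inter-copy region
    is searched for a truncated entrance-palindrome match of at least
    6 nt — the internal target-site evidence that distinguishes two tandem
    insertions from one fused double-length element.  More than two copies
    is reported as an unsupported structure.
    """
    oriented = _oriented(insert_seq, orientation)
    floor = floor_fraction * scoring.match * element.length
    masked = oriented
    hits: list[tuple[int, int]] = []
    flags: list[str] = []
    for _round in range(4):
        hit = local_align(element.sequence, masked, scoring)
        if hit.score < floor:
            break
        hits.append((hit.query_start, hit.query_end))
        masked = (
            masked[: hit.query_start]
            + "N" * (hit.query_end - hit.query_start)
            + masked[hit.query_end :]
        )
    hits.sort()
    if len(hits) > 2:
        flags.append("unsupported_structure")
        return TandemResult(len(hits), hits, None, flags)
    evidence = None
    if len(hits) == 2:
        gap_lo, gap_hi = hits[0][1], hits[1][0]
        between = oriented[gap_lo:gap_hi]
        for template in tsd_templates or []:
            candidates = [template.sequence] + [
                template.allele_sequence(a) for a in template.named_alleles
            ]
            for cand in candidates:
                k, i, _j = _longest_common_substring_position(between, cand)
                if k >= MIN_INTERNAL_TSD_MATCH:
                    iv = (gap_lo + i, gap_lo + i + k)
                    if evidence is None or (iv[1] - iv[0]) > (evidence[1] - evidence[0]):
                        evidence = iv
        if evidence is None:
            flags.append("bov_a4_like")
    return TandemResult(len(hits), hits, evidence, flags)


@dataclasses.dataclass
class MonomerAssignment:
    segment: str  # "monomer1" | "monomer2" (the decomposed slot)
    assigned: str  # "monomer1" | "monomer2" | "ambiguous"
    votes_monomer1: int
    votes_monomer2: int


def classify_monomers(
    annotation: ComponentAnnotation,
    element: ElementModel,
) -> list[MonomerAssignment]:
    """Assign each monomer segment by majority vote over diagnostic sites.

    For every diagnostic site the aligned insert base at the monomer-1 and
    monomer-2 consensus positions votes for the matching monomer identity;
    a tied vote yields an explicit "ambiguous" assignment, never an
    arbitrary one.
    """
    if annotation.is_partial and {"monomer1", "monomer2"} & set(annotation.missing_components):
        raise ValueError("cannot classify monomers of a partial element")
    coord = dict(annotation.alignment.coordinate_map())  # consensus -> insert
    oriented = annotation.oriented_sequence
    m2_start = len(element.monomer1) + len(element.linker)
    out = []
    for segment, base_offset in (("monomer1", 0), ("monomer2", m2_start)):
        v1 = v2 = 0
        for off, b1, b2 in element.diagnostic_sites:
            if segment == "monomer1":
                cpos = base_offset + off
            else:
                cpos = base_offset + element._m2_offset(off)
            qpos = coord.get(cpos)
            if qpos is None:
                continue
            base = oriented[qpos]
            if base == b1:
                v1 += 1
            elif base == b2:
                v2 += 1
        if v1 > v2:
            assigned = "monomer1"
        elif v2 > v1:
            assigned = "monomer2"
        else:
            assigned = "ambiguous"
        out.append(MonomerAssignment(segment, assigned, v1, v2))
    return out


@dataclasses.dataclass
class VariantCall:
    """A difference against the consensus, on consensus coordinates (1-based),
    reported on the consensus strand regardless of insertion orientation."""

    copy_index: int
    position: int
    kind: str  # substitution | deletion | insertion
    consensus_bases: str
    observed_bases: str


def call_variants(
    insert_seq: str,
    element: ElementModel,
    orientation: str,
    copy_index: int = 1,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[VariantCall]:
    """Variants of one element copy against the consensus.

    The oriented insert is globally aligned to the consensus; substitutions,
    deletions and insertions are reported at 1-based consensus positions.
    Query-only runs touching the insert boundaries are flanking target-site
    remnants, not element variants, and are excluded.
    """
    oriented = _oriented(insert_seq, orientation)
    aln = global_align(element.sequence, oriented, scoring, "consensus", "insert")
    variants = []
    for ref_pos, q_pos in aln.mismatch_columns():
        variants.append(
            VariantCall(
                copy_index=copy_index,
                position=ref_pos + 1,
                kind="substitution",
                consensus_bases=element.sequence[ref_pos],
                observed_bases=oriented[q_pos],
            )
        )
    for run in aln.reference_only_runs():
        # interval lives on the consensus (deleted consensus bases)
        lo, hi = run.query_start, run.query_end
        variants.append(
            VariantCall(
                copy_index=copy_index,
                position=lo + 1,
                kind="deletion",
                consensus_bases=element.sequence[lo:hi],
                observed_bases="-",
            )
        )
    for run in aln.query_only_runs():
        if run.query_start == 0 or run.query_end == len(oriented):
            continue  # flanking target-site remnant
        variants.append(
            VariantCall(
                copy_index=copy_index,
                position=run.ref_position + 1,
                kind="insertion",
                consensus_bases="-",
                observed_bases=oriented[run.query_start : run.query_end],
            )
        )
    variants.sort(key=lambda v: (v.position, v.kind))
    return variants


def summarize_variant_sharing(
    variants_by_species: dict[str, list[VariantCall]],
    clades: dict[str, str] | None = None,
) -> list[dict]:
    """Group identical variants across species into shared vs private calls."""
    groups: dict[tuple, list[str]] = {}
    for species, variants in variants_by_species.items():
        for v in variants:
            key = (v.copy_index, v.position, v.kind, v.consensus_bases, v.observed_bases)
            groups.setdefault(key, []).append(species)
    rows = []
    for key in sorted(groups):
        species = sorted(groups[key])
        copy_index, position, kind, cons, obs = key
        row = {
            "copy_index": copy_index,
            "position": position,
            "kind": kind,
            "consensus": cons,
            "observed": obs,
            "species": ",".join(species),
            "sharing": "shared" if len(species) > 1 else "private",
        }
        if clades:
            row["clades"] = ",".join(sorted({clades.get(s, "?") for s in species}))
        rows.append(row)
    return rows
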