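"""Insertion calling from pairwise comparison of orthologous promoters.

Each query promoter is globally aligned to an insertion-free reference; a
query-only gap run at least ``min_insertion_length`` long is called as an
insertion, anchored to the reference TSS.  Calls across species are then
clustered into loci by reference position.
"""

from __future__ import annotations

import dataclasses

from .align import DEFAULT_SCORING, PairwiseAlignment, Scoring, global_align
from .io_formats import SequenceRecord
from .panel import Panel, PromoterRecord

DEFAULT_MIN_INSERTION_LENGTH = 50
DEFAULT_LOCUS_TOLERANCE = 5


def _as_record(obj) -> SequenceRecord:
    if isinstance(obj, PromoterRecord):
        return obj.record
    if isinstance(obj, SequenceRecord):
        return obj
    raise TypeError(f"expected a sequence record, got {type(obj).__name__}")


def align_pair(
    reference, query, scoring: Scoring = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Optimal global alignment of a query promoter against the reference."""
    ref = _as_record(reference)
    qry = _as_record(query)
    return global_align(
        ref.sequence,
        qry.sequence,
        scoring,
        reference_id=ref.identifier,
        query_id=qry.identifier,
    )


@dataclasses.dataclass
class InsertionCall:
    """A called insertion in one query relative to the reference.

    ``ref_position`` is the 0-based reference coordinate immediately after
    which the inserted material sits (3'-normalized); ``tss_distance`` is nt
    upstream (positive) of the reference TSS.
    """

    query_id: str
    ref_position: int
    tss_distance: int
    length: int
    inserted_sequence: str
    query_start: int
    query_end: int

    def __post_init__(self) -> None:
        if self.length != len(self.inserted_sequence):
            raise ValueError("insertion length disagrees with its sequence")


def call_insertions(
    alignment: PairwiseAlignment,
    reference_tss: int | None,
    min_insertion_length: int = DEFAULT_MIN_INSERTION_LENGTH,
) -> list[InsertionCall]:
    """Insertions: query-only gap runs of at least ``min_insertion_length``."""
    if reference_tss is None:
        raise ValueError("reference TSS anchor is required to place insertion calls")
    calls = []
    for run in alignment.query_only_runs():
        if run.length < min_insertion_length:
            continue
        calls.append(
            InsertionCall(
                query_id=alignment.query_id,
                ref_position=run.ref_position,
                tss_distance=reference_tss - run.ref_position,
                length=run.length,
                inserted_sequence=alignment.query[run.query_start : run.query_end],
                query_start=run.query_start,
                query_end=run.query_end,
            )
        )
    return calls


@dataclasses.dataclass
class Locus:
    """A cluster of insertion calls sharing a reference position."""

    label: str
    position: float  # mean reference position of the member calls
    calls: list[InsertionCall]

    @property
    def species(self) -> list[str]:
        return sorted({c.query_id for c in self.calls})


@dataclasses.dataclass
class LocusTable:
    loci: list[Locus]

    def distances(self) -> dict[tuple[str, str], float]:
        out = {}
        for a in self.loci:
            for b in self.loci:
                if a.label < b.label:
                    out[(a.label, b.label)] = abs(b.position - a.position)
        return out


def compare_loci(
    calls_by_species: dict[str, list[InsertionCall]],
    tolerance: int = DEFAULT_LOCUS_TOLERANCE,
) -> LocusTable:
    """Cluster calls into loci by reference position (single linkage).

    Calls whose reference positions are within ``tolerance`` nt of a cluster
    member join that cluster; loci are labelled IS1, IS2, ... in reference
    order and positioned at the cluster mean.
    """
    calls = [c for lst in calls_by_species.values() for c in lst]
    if not calls:
        raise ValueError("compare_loci requires at least one insertion call")
    calls.sort(key=lambda c: (c.ref_position, c.query_id))
    clusters: list[list[InsertionCall]] = [[calls[0]]]
    for call in calls[1:]:
        if call.ref_position - clusters[-1][-1].ref_position <= tolerance:
            clusters[-1].append(call)
        else:
            clusters.append([call])
    loci = []
    for k, members in enumerate(clusters, 1):
        position = sum(c.ref_position for c in members) / len(members)
        loci.append(Locus(label=f"IS{k}", position=position, calls=members))
    return LocusTable(loci)


def call_panel(
    panel: Panel,
    reference: str = "cow",
    scoring: Scoring = DEFAULT_SCORING,
    min_insertion_length: int = DEFAULT_MIN_INSERTION_LENGTH,
) -> dict[str, list[InsertionCall]]:
    """Call insertions for every non-reference species against the reference."""
    ref = panel.by_name(reference)
    out: dict[str, list[InsertionCall]] = {}
    for rec in panel.records:
        if rec.identifier == reference:
            continue
        aln = align_pair(ref, rec, scoring)
        out[rec.identifier] = call_insertions(
            aln, ref.tss_position, min_insertion_length
        )
    return out
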