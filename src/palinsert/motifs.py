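"""Position-weight-matrix scanning and element-unique motif classification.

Generic log-odds PWM scanning of promoter regions on both strands, followed
by a simple spatial classification: a motif is *element-unique* when it hits
inside the inserted element and nowhere else in the analyzed promoter
region — the signature of a binding site gained by the insertion.  Motif
matrices are user-supplied (JASPAR counts); a small synthetic set ships for
testing.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .align import encode_dna
from .io_formats import CountMatrix, reverse_complement

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_THRESHOLD_FRACTION = 0.8


@dataclasses.dataclass
class PwmModel:
    """Log-odds matrix in bits with its score threshold."""

    motif_id: str
    log_odds: np.ndarray  # shape (4, width), rows A/C/G/T
    background: np.ndarray
    threshold: float

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())


def pwm_from_counts(
    counts: CountMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> PwmModel:
    """Log-odds PWM from base counts.

    Each column's probabilities are (count + pseudocount) / (total + 4 x
    pseudocount); log-odds are log2(p / background).  The default threshold
    is ``threshold_fraction`` of the maximum attainable score.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    c = counts.counts
    if (c < 0).any():
        raise ValueError(f"{counts.motif_id}: negative counts")
    if (c.sum(axis=0) == 0).any():
        raise ValueError(f"{counts.motif_id}: all-zero column")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    probs = (c + pseudocount) / (c.sum(axis=0, keepdims=True) + 4 * pseudocount)
    log_odds = np.log2(probs / background[:, None])
    model = PwmModel(counts.motif_id, log_odds, background, threshold=0.0)
    model.threshold = threshold_fraction * model.max_score
    return model


@dataclasses.dataclass
class MotifHit:
    motif_id: str
    sequence_id: str
    start: int
    end: int  # forward-strand coordinates, half-open
    strand: str
    score: float
    inside_element: bool = False


def scan(seq: str, pwm: PwmModel, sequence_id: str = "seq") -> list[MotifHit]:
    """All windows on both strands scoring at or above the PWM threshold.

    Windows containing N are skipped.  Minus-strand hits are reported on
    forward-strand coordinates.
    """
    w = pwm.width
    if len(seq) < w:
        raise ValueError("sequence shorter than the motif width")
    hits = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        codes = encode_dna(s)
        n = len(s)
        lo = pwm.log_odds
        for start in range(n - w + 1):
            window = codes[start : start + w]
            if (window == 4).any():
                continue
            score = float(lo[window, np.arange(w)].sum())
            if score >= pwm.threshold:
                if strand == "+":
                    iv = (start, start + w)
                else:
                    iv = (n - start - w, n - start)
                hits.append(
                    MotifHit(pwm.motif_id, sequence_id, iv[0], iv[1], strand, score)
                )
    hits.sort(key=lambda h: (h.start, h.strand, h.motif_id))
    return hits


@dataclasses.dataclass
class MotifClassification:
    motif_id: str
    category: str  # element_unique | shared | background_only | absent
    inside_count: int
    outside_count: int

    @property
    def enrichment(self) -> str:
        return f"{self.inside_count}:{self.outside_count}"


def element_unique_hits(
    hits: list[MotifHit],
    element_intervals: list[tuple[int, int]],
    region: tuple[int, int],
    motif_ids: list[str] | None = None,
) -> dict[str, MotifClassification]:
    """Classify motifs by where their hits fall within the analyzed region.

    ``region`` is the analyzed promoter interval (conventionally the CpG
    island start through TSS+50); hits outside it are ignored.  A motif is
    element-unique iff at least one hit lies entirely within an element
    interval and none lie elsewhere in the region.  The classification is a
    partition: every motif gets exactly one category.
    """
    r_lo, r_hi = region
    if r_lo >= r_hi:
        raise ValueError("empty analyzed region")
    for lo, hi in element_intervals:
        if not (r_lo <= lo < hi <= r_hi):
            raise ValueError(
                f"element interval [{lo}, {hi}) outside the analyzed region {region}"
            )
    ids = motif_ids if motif_ids is not None else sorted({h.motif_id for h in hits})
    out = {}
    for motif_id in ids:
        inside = outside = 0
        for h in hits:
            if h.motif_id != motif_id:
                continue
            if not (r_lo <= h.start and h.end <= r_hi):
                continue
            if any(lo <= h.start and h.end <= hi for lo, hi in element_intervals):
                inside += 1
                h.inside_element = True
            else:
                outside += 1
        if inside and not outside:
            category = "element_unique"
        elif inside and outside:
            category = "shared"
        elif outside:
            category = "background_only"
        else:
            category = "absent"
        out[motif_id] = MotifClassification(motif_id, category, inside, outside)
    return out
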