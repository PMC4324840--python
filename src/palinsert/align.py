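"""Pairwise DNA alignment with affine gaps and deterministic tie-breaking.

Global alignment (Gotoh) drives insertion calling; local alignment
(Smith-Waterman) drives element orientation and tandem-copy detection.  Both
are numba-compiled; sequences here are promoter-scale (a few kb) so a full
dynamic-programming matrix is cheap.

Tie-breaking is deterministic and 3'-normalized: among co-optimal alignments,
gaps are placed as far to the 3' (right) end as the optimum allows.  A target
site duplication makes an insertion's placement ambiguous by exactly the
length of the duplicated copy; right-normalization anchors the call at the
entrance site downstream of the retained target copy, which is the convention
the rest of the pipeline (and the locus-distance bookkeeping) relies on.

``N`` never matches anything, including itself.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

NEG = np.float32(-1e30)


_ENCODE_LUT = np.full(256, 4, dtype=np.int8)
for _b, _c in _BASE_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c


def encode_dna(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N as 0..4 (int8)."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _ENCODE_LUT[raw]


@dataclasses.dataclass(frozen=True)
class Scoring:
    """Alignment scoring: affine gap of length L costs ``gap_open + L*gap_extend``."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -6.0
    gap_extend: float = -1.0

    def substitution_matrix(self) -> np.ndarray:
        m = np.full((5, 5), self.mismatch, dtype=np.float32)
        for i in range(4):
            m[i, i] = self.match
        m[4, :] = self.mismatch  # N never matches
        m[:, 4] = self.mismatch
        return m


DEFAULT_SCORING = Scoring()

# op codes in the traceback path
OP_MATCH = 0  # ref and query both consumed
OP_REF_ONLY = 1  # ref consumed, query gap (deletion from the query)
OP_QUERY_ONLY = 2  # query consumed, ref gap (insertion in the query)


@njit(cache=True)
def _gotoh_fill(x, y, sub, gap_open, gap_extend):
    n = x.shape[0]
    m = y.shape[0]
    M = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    D = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # ends with ref-only column
    I = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # ends with query-only column
    # traceback: predecessor state for each state (0=M,1=D,2=I, -1=start)
    tbM = np.full((n + 1, m + 1), -1, dtype=np.int8)
    tbD = np.full((n + 1, m + 1), -1, dtype=np.int8)
    tbI = np.full((n + 1, m + 1), -1, dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        D[i, 0] = gap_open + gap_extend * i
        tbD[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        I[0, j] = gap_open + gap_extend * j
        tbI[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            s = sub[xi, y[j - 1]]
            # M: prefer predecessor I, then D, then M (3'-normalizes gaps)
            best = I[i - 1, j - 1]
            state = 2
            if D[i - 1, j - 1] > best:
                best = D[i - 1, j - 1]
                state = 1
            if M[i - 1, j - 1] > best:
                best = M[i - 1, j - 1]
                state = 0
            M[i, j] = best + s
            tbM[i, j] = state
            # D: ref-only column; prefer continuing the gap on ties
            best = D[i - 1, j] + gap_extend
            state = 1
            alt = I[i - 1, j] + gap_open + gap_extend
            if alt > best:
                best = alt
                state = 2
            alt = M[i - 1, j] + gap_open + gap_extend
            if alt > best:
                best = alt
                state = 0
            D[i, j] = best
            tbD[i, j] = state
            # I: query-only column; prefer continuing the gap on ties
            best = I[i, j - 1] + gap_extend
            state = 2
            alt = D[i, j - 1] + gap_open + gap_extend
            if alt > best:
                best = alt
                state = 1
            alt = M[i, j - 1] + gap_open + gap_extend
            if alt > best:
                best = alt
                state = 0
            I[i, j] = best
            tbI[i, j] = state
    return M, D, I, tbM, tbD, tbI


@njit(cache=True)
def _gotoh_traceback(M, D, I, tbM, tbD, tbI, n, m):
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    # final state: prefer I, then D, then M on ties (rightmost gaps)
    state = 2
    best = I[n, m]
    if D[n, m] > best:
        best = D[n, m]
        state = 1
    if M[n, m] > best:
        best = M[n, m]
        state = 0
    score = best
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = tbM[i, j]
            ops[k] = OP_MATCH
            i -= 1
            j -= 1
        elif state == 1:
            prev = tbD[i, j]
            ops[k] = OP_REF_ONLY
            i -= 1
        else:
            prev = tbI[i, j]
            ops[k] = OP_QUERY_ONLY
            j -= 1
        k += 1
        state = prev
    return score, ops[:k][::-1].copy()


@dataclasses.dataclass
class GapRun:
    """A maximal run of gap columns: ``ref_position`` is the 0-based reference
    coordinate immediately after which the run sits."""

    ref_position: int
    query_start: int
    query_end: int

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


@dataclasses.dataclass
class PairwiseAlignment:
    """A global alignment of a query against a reference."""

    reference_id: str
    query_id: str
    score: float
    ops: np.ndarray  # int8 vector of OP_* codes, 5'->3'
    reference: str
    query: str

    def query_only_runs(self) -> list[GapRun]:
        """Maximal runs of query-only columns (candidate insertions)."""
        return self._runs(OP_QUERY_ONLY)

    def reference_only_runs(self) -> list[GapRun]:
        """Maximal runs of reference-only columns (candidate deletions).

        The interval (``query_start``/``query_end`` fields) lives on the
        *reference*; ``ref_position`` is the anchoring query coordinate.
        """
        runs: list[GapRun] = []
        i = j = 0  # ref, query cursors
        start = None
        for op in self.ops:
            if op == OP_REF_ONLY:
                if start is None:
                    start = (j, i)
                i += 1
            else:
                if start is not None:
                    runs.append(GapRun(start[0], start[1], i))
                    start = None
                if op == OP_MATCH:
                    i += 1
                    j += 1
                else:
                    j += 1
        if start is not None:
            runs.append(GapRun(start[0], start[1], i))
        return runs

    def _runs(self, which: int) -> list[GapRun]:
        runs: list[GapRun] = []
        i = j = 0  # ref, query cursors
        start = None
        for op in self.ops:
            if op == which:
                if start is None:
                    start = (i, j)
                j += 1
            else:
                if start is not None:
                    runs.append(GapRun(start[0], start[1], j))
                    start = None
                if op == OP_MATCH:
                    i += 1
                    j += 1
                else:
                    i += 1
        if start is not None:
            runs.append(GapRun(start[0], start[1], j))
        return runs

    def mismatch_columns(self) -> list[tuple[int, int]]:
        """(ref_pos, query_pos) of aligned columns with differing bases."""
        out = []
        i = j = 0
        for op in self.ops:
            if op == OP_MATCH:
                if self.reference[i] != self.query[j] or self.reference[i] == "N":
                    out.append((i, j))
                i += 1
                j += 1
            elif op == OP_REF_ONLY:
                i += 1
            else:
                j += 1
        return out

    def coordinate_map(self) -> list[tuple[int, int]]:
        """Monotone (ref_pos, query_pos) pairs for aligned (non-gap) columns."""
        out = []
        i = j = 0
        for op in self.ops:
            if op == OP_MATCH:
                out.append((i, j))
                i += 1
                j += 1
            elif op == OP_REF_ONLY:
                i += 1
            else:
                j += 1
        return out


def global_align(
    reference: str,
    query: str,
    scoring: Scoring = DEFAULT_SCORING,
    reference_id: str = "ref",
    query_id: str = "query",
) -> PairwiseAlignment:
    """Optimal global alignment under affine-gap scoring.

    Deterministic: among co-optimal alignments gaps are placed rightmost
    (3'-normalized) and kept contiguous.
    """
    if not reference or not query:
        raise ValueError("global_align requires two non-empty sequences")
    x = encode_dna(reference)
    y = encode_dna(query)
    sub = scoring.substitution_matrix()
    M, D, I, tbM, tbD, tbI = _gotoh_fill(
        x, y, sub, np.float32(scoring.gap_open), np.float32(scoring.gap_extend)
    )
    score, ops = _gotoh_traceback(M, D, I, tbM, tbD, tbI, len(x), len(y))
    return PairwiseAlignment(reference_id, query_id, float(score), ops, reference, query)


@njit(cache=True)
def _sw_fill(x, y, sub, gap_open, gap_extend):
    n = x.shape[0]
    m = y.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.float32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    # traceback pointers: tbH 0=diag 1=E 2=F 3=local-start; tbE/tbF 0=open 1=extend
    tbH = np.full((n + 1, m + 1), 3, dtype=np.int8)
    tbE = np.zeros((n + 1, m + 1), dtype=np.int8)
    tbF = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = np.float32(0.0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + gap_extend
            eo = H[i, j - 1] + gap_open + gap_extend
            if e > eo:
                E[i, j] = e
                tbE[i, j] = 1
            else:
                E[i, j] = eo
                tbE[i, j] = 0
            f = F[i - 1, j] + gap_extend
            fo = H[i - 1, j] + gap_open + gap_extend
            if f > fo:
                F[i, j] = f
                tbF[i, j] = 1
            else:
                F[i, j] = fo
                tbF[i, j] = 0
            h = H[i - 1, j - 1] + sub[xi, y[j - 1]]
            ptr = 0
            if E[i, j] > h:
                h = E[i, j]
                ptr = 1
            if F[i, j] > h:
                h = F[i, j]
                ptr = 2
            if h <= 0.0:
                h = 0.0
                ptr = 3
            H[i, j] = h
            tbH[i, j] = ptr
            if h > best:
                best = h
                bi = i
                bj = j
    return tbH, tbE, tbF, best, bi, bj


@njit(cache=True)
def _sw_traceback(tbH, tbE, tbF, bi, bj):
    i, j = bi, bj
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            ptr = tbH[i, j]
            if ptr == 3:
                break
            if ptr == 0:
                i -= 1
                j -= 1
            else:
                state = ptr
        elif state == 1:
            ptr = tbE[i, j]
            j -= 1
            state = 0 if ptr == 0 else 1
        else:
            ptr = tbF[i, j]
            i -= 1
            state = 0 if ptr == 0 else 2
    return i, j


@dataclasses.dataclass
class LocalHit:
    score: float
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int


def local_align(
    reference: str, query: str, scoring: Scoring = DEFAULT_SCORING
) -> LocalHit:
    """Best local alignment (Smith-Waterman) of query against reference."""
    if not reference or not query:
        return LocalHit(0.0, 0, 0, 0, 0)
    x = encode_dna(reference)
    y = encode_dna(query)
    sub = scoring.substitution_matrix()
    go = np.float32(scoring.gap_open)
    ge = np.float32(scoring.gap_extend)
    tbH, tbE, tbF, best, bi, bj = _sw_fill(x, y, sub, go, ge)
    if best <= 0.0:
        return LocalHit(0.0, 0, 0, 0, 0)
    si, sj = _sw_traceback(tbH, tbE, tbF, bi, bj)
    return LocalHit(float(best), si, bi, sj, bj)
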