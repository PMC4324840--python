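"""Target-site duplications, palindrome-copy truncation, insertion relics.

A retroposon insertion by non-equal homologous recombination leaves a
duplicated (usually truncated) copy of the entrance sequence on the 3' flank
of the element.  This module finds such duplications between the element's
flanking windows, classifies on which side a palindrome copy is truncated,
and detects secondary-insertion relics (a long poly-A run followed by a
partial entrance-palindrome) inside an element's terminator.
"""

from __future__ import annotations

import dataclasses

from .align import local_align
from .annotate import ComponentAnnotation
from .palindrome import PalindromeTemplate

DEFAULT_MIN_TSD_LENGTH = 8
DEFAULT_TSD_MAX_MISMATCHES = 1
DEFAULT_TSD_WINDOW = 30
DEFAULT_MIN_POLYA = 11  # "more than 10 nucleotides long" is a strict bound
DEFAULT_MIN_PARTIAL = 6
RELIC_MAX_GAP = 3


@dataclasses.dataclass
class TsdCall:
    """A duplicated target sequence flanking an insertion.

    Intervals are relative to the supplied flank windows: the 5' copy within
    ``flank5`` (its last ``window`` nt), the 3' copy within ``flank3``.
    """

    duplicated_sequence: str
    five_prime_interval: tuple[int, int]
    three_prime_interval: tuple[int, int]
    match_length: int
    mismatches: int


def find_tsd(
    flank5: str,
    flank3: str,
    min_tsd_length: int = DEFAULT_MIN_TSD_LENGTH,
    max_mismatches: int = DEFAULT_TSD_MAX_MISMATCHES,
    window: int = DEFAULT_TSD_WINDOW,
) -> TsdCall | None:
    """Longest shared near-exact substring between the two flank windows.

    Windows are the last ``window`` nt of the 5' flank and the first
    ``window`` nt of the 3' flank.  Mismatches (up to ``max_mismatches``) are
    internal only, so the reported duplication never starts or ends on a
    mismatch; ``N`` never matches.  Returns None below ``min_tsd_length``.
    Ties prefer the copy pair closest to the insertion boundaries.
    """
    a = flank5[-window:]
    b = flank3[:window]
    if len(a) < min_tsd_length or len(b) < min_tsd_length:
        return None
    best = None  # (length, proximity, i, j, mismatches)
    for i in range(len(a)):
        for j in range(len(b)):
            # extend a match from (i, j) allowing internal mismatches
            length = 0
            mm_positions: list[int] = []
            k = 0
            while i + k < len(a) and j + k < len(b):
                ai, bj = a[i + k], b[j + k]
                if ai == bj and ai != "N":
                    k += 1
                    continue
                if len(mm_positions) + 1 > max_mismatches:
                    break
                mm_positions.append(k)
                k += 1
            # trim trailing mismatches
            while mm_positions and mm_positions[-1] == k - 1:
                mm_positions.pop()
                k -= 1
            if mm_positions and mm_positions[0] == 0:
                continue
            if k < min_tsd_length:
                continue
            proximity = (len(a) - (i + k)) + j  # distance from the boundaries
            cand = (-k, proximity, j, i)
            if best is None or cand < best[0]:
                best = (cand, i, j, k, len(mm_positions))
    if best is None:
        return None
    _key, i, j, k, n_mm = best
    return TsdCall(
        duplicated_sequence=b[j : j + k],
        five_prime_interval=(i, i + k),
        three_prime_interval=(j, j + k),
        match_length=k,
        mismatches=n_mm,
    )


@dataclasses.dataclass
class TruncationReport:
    """Which side(s) of a palindrome copy are missing, by alignment to the
    full template — derived, not guessed."""

    copy_id: str
    recognizable: bool
    truncated_5prime: bool
    truncated_3prime: bool
    retained_fraction: float


def classify_truncation(
    observed_copy: str,
    template: PalindromeTemplate | str,
    allele: str | None = None,
    copy_id: str = "copy",
) -> TruncationReport:
    """Truncation sidedness of an observed palindrome copy.

    The copy is locally aligned to the full template sequence (or a named
    allele of it); the truncation flags record whether the alignment reaches
    the template's first/last position.  A copy retaining less than half of
    the template is reported unrecognizable.
    """
    if isinstance(template, PalindromeTemplate):
        full = template.allele_sequence(allele)
    else:
        full = template
    if not observed_copy:
        raise ValueError("empty observed copy")
    hit = local_align(full, observed_copy)
    retained = (hit.ref_end - hit.ref_start) / len(full)
    if retained < 0.5:
        return TruncationReport(copy_id, False, False, False, retained)
    return TruncationReport(
        copy_id=copy_id,
        recognizable=True,
        truncated_5prime=hit.ref_start > 0,
        truncated_3prime=hit.ref_end < len(full),
        retained_fraction=retained,
    )


@dataclasses.dataclass
class RelicReport:
    """A secondary-insertion relic inside an element terminator: a poly-A run
    immediately followed by a partial entrance-palindrome."""

    polya_interval: tuple[int, int]  # oriented-insert coordinates
    partial_interval: tuple[int, int]
    template_name: str
    matched_length: int
    matched_end: str  # "prefix" or "suffix" of the template
    terminator_repeats_before: int
    terminator_repeats_after: int


def detect_relic(
    annotation: ComponentAnnotation,
    palindrome_templates: list[PalindromeTemplate],
    min_polya: int = DEFAULT_MIN_POLYA,
    min_partial: int = DEFAULT_MIN_PARTIAL,
) -> RelicReport | None:
    """Poly-A + partial-palindrome relic between terminator repeats.

    Scans the element tail (from the terminator's aligned start) for a
    poly-A run of at least ``min_polya`` nt followed within
    ``RELIC_MAX_GAP`` nt by a match of at least ``min_partial`` nt to a
    prefix or suffix of any supplied template.  Reports the hosting position
    as the number of terminator repeats before/after the relic.
    """
    if min_polya <= 10:
        raise ValueError("the poly-A bound is strict: min_polya must be > 10")
    seq = annotation.oriented_sequence
    t_lo, _ = annotation.intervals.get("terminator", (None, None))
    if t_lo is None or "terminator" in annotation.missing_components:
        return None
    unit_len = len("AGC")
    tail = seq[t_lo:]
    # poly-A runs in the tail
    runs = []
    k = 0
    while k < len(tail):
        if tail[k] == "A":
            start = k
            while k < len(tail) and tail[k] == "A":
                k += 1
            if k - start >= min_polya:
                runs.append((start, k))
        else:
            k += 1
    for start, end in runs:
        for gap in range(RELIC_MAX_GAP + 1):
            probe = tail[end + gap :]
            if not probe:
                continue
            for template in palindrome_templates:
                full = template.sequence
                best_len = 0
                best_end = ""
                for klen in range(len(full), min_partial - 1, -1):
                    if probe.startswith(full[:klen]):
                        best_len, best_end = klen, "prefix"
                        break
                if not best_len:
                    for klen in range(len(full), min_partial - 1, -1):
                        if probe.startswith(full[-klen:]):
                            best_len, best_end = klen, "suffix"
                            break
                if not best_len:
                    continue
                repeats_before = _count_repeats(tail[:start])
                after_start = end + gap + best_len
                repeats_after = _count_repeats(tail[after_start:])
                return RelicReport(
                    polya_interval=(t_lo + start, t_lo + end),
                    partial_interval=(t_lo + end + gap, t_lo + after_start),
                    template_name=template.name,
                    matched_length=best_len,
                    matched_end=best_end,
                    terminator_repeats_before=repeats_before,
                    terminator_repeats_after=repeats_after,
                )
    return None


def _count_repeats(seq: str, unit: str = "AGC") -> int:
    count = 0
    k = 0
    while seq[k : k + len(unit)] == unit:
        count += 1
        k += len(unit)
    return count
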