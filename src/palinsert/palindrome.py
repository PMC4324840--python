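"""Near-palindrome (inverted repeat) detection and hairpin thermodynamics.

A DNA near-palindrome is a segment whose 5' arm is the reverse complement of
its 3' arm around a short central loop, up to a small number of internal
mismatches.  Such segments can fold into stem-loop (hairpin) structures; the
stability of the hairpin is scored with a hairpin-only nearest-neighbor model:
the free energy is the sum of stack terms over consecutive Watson-Crick pairs,
a loop-initiation term for the terminal loop, and simple penalties for
internal mismatches (treated as 1x1 internal loops) and bulges.  Multibranch
structures, suboptimal ensembles and partition functions are out of scope.

Length convention: a palindrome's reported length is the full genomic span,
loop included (an "18 bp palindrome" occupies 18 nt of sequence).
"""

from __future__ import annotations

import dataclasses
import json
import math
from importlib import resources

from .io_formats import normalize_sequence

WATSON_CRICK = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def is_wc(a: str, b: str) -> bool:
    """Watson-Crick pair test.  N never pairs."""
    return (a, b) in WATSON_CRICK


# ---------------------------------------------------------------------------
# Energy model


@dataclasses.dataclass
class EnergyModel:
    """Nearest-neighbor hairpin free-energy parameters (kcal/mol, 37 C)."""

    stack: dict[str, float]
    hairpin_loop: dict[int, float]
    mismatch_penalty: float
    bulge_penalty: float
    extrapolation_per_nt: float
    temperature: float = 37.0

    def __post_init__(self) -> None:
        missing = {
            a + b
            for a in "ACGT"
            for b in "ACGT"
        } - set(self.stack)
        if missing:
            raise ValueError(f"stack table incomplete, missing steps {sorted(missing)}")
        for n in range(3, 31):
            if n not in self.hairpin_loop:
                raise ValueError(f"hairpin loop table missing length {n}")

    def loop_init(self, loop_len: int) -> float:
        """Loop initiation energy; loops shorter than 3 nt are charged as a
        strained 3-nt loop, loops beyond 30 nt extrapolate monotonically."""
        if loop_len <= 3:
            return self.hairpin_loop[3]
        if loop_len <= 30:
            return self.hairpin_loop[loop_len]
        return self.hairpin_loop[30] + self.extrapolation_per_nt * (loop_len - 30)

    @classmethod
    def default(cls) -> "EnergyModel":
        with resources.files("palinsert.data").joinpath("nn_dna_dG37.json").open() as fh:
            raw = json.load(fh)
        return cls(
            stack=raw["stack"],
            hairpin_loop={int(k): v for k, v in raw["hairpin_loop"].items()},
            mismatch_penalty=raw["mismatch_penalty"],
            bulge_penalty=raw["bulge_penalty"],
            extrapolation_per_nt=raw["extrapolation_per_nt"],
            temperature=raw["temperature_celsius"],
        )


_DEFAULT_MODEL: EnergyModel | None = None


def default_energy_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = EnergyModel.default()
    return _DEFAULT_MODEL


def hairpin_dG(seq: str, pairing: list[tuple[int, int]], model: EnergyModel | None = None) -> float:
    """Free energy of a single stem-loop with the given pairing.

    ``pairing`` lists (i, j) pairs, 1-based within ``seq``, i < j.  Pairs must
    be non-crossing (a single stem-loop, bulges allowed).  Mismatched pairs
    contribute a 1x1 internal-loop penalty and interrupt stacking; each bulge
    run contributes a flat penalty.  Input with no Watson-Crick pair cannot
    fold and is reported as math.inf ("no stable hairpin").
    """
    model = model or default_energy_model()
    seq = normalize_sequence(seq)
    if not pairing:
        return math.inf
    pairs = sorted(pairing)
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 < j2 < j1):
            raise ValueError(f"crossing or non-nested pairs ({i1},{j1}) and ({i2},{j2})")
    for i, j in pairs:
        if not (1 <= i < j <= len(seq)):
            raise ValueError(f"pair ({i},{j}) outside sequence of length {len(seq)}")
    wc_flags = [is_wc(seq[i - 1], seq[j - 1]) for i, j in pairs]
    if not any(wc_flags):
        return math.inf
    dg = 0.0
    for (i1, j1), (i2, j2), wc1, wc2 in zip(pairs, pairs[1:], wc_flags, wc_flags[1:]):
        contiguous = i2 == i1 + 1 and j2 == j1 - 1
        if contiguous and wc1 and wc2:
            dg += model.stack[seq[i1 - 1] + seq[i2 - 1]]
        elif not contiguous:
            dg += model.bulge_penalty
    dg += model.mismatch_penalty * (len(pairs) - sum(wc_flags))
    inner_i, inner_j = pairs[-1]
    dg += model.loop_init(inner_j - inner_i - 1)
    return dg


# ---------------------------------------------------------------------------
# Detection


@dataclasses.dataclass
class Palindrome:
    """A near-palindromic locus detected in a sequence.

    ``start``/``end`` are 0-based half-open in the scanned sequence; pairing
    positions and ``mismatch_positions`` are 1-based within the span.
    """

    sequence_id: str
    start: int
    end: int
    arm_length: int
    loop_length: int
    pairing: list[tuple[int, int]]
    mismatch_positions: list[int]
    delta_g: float

    @property
    def total_length(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def find_palindromes(
    seq: str,
    min_total_length: int = 10,
    max_loop: int = 4,
    max_mismatches: int = 1,
    sequence_id: str = "seq",
    model: EnergyModel | None = None,
) -> list[Palindrome]:
    """All locally-longest near-palindromes meeting the thresholds.

    Center-and-loop enumeration: for every loop placement of size 0..max_loop
    the arms are extended outward while the mismatch budget allows, then
    trimmed so neither arm boundary sits on a mismatch.  A candidate is
    dropped when a strictly longer candidate overlaps it; among identical
    spans the partition with fewest mismatches, then smallest loop, is kept.
    The selection rule is symmetric under reverse complement.
    """
    seq = normalize_sequence(seq)
    n = len(seq)
    model = model or default_energy_model()
    best_by_span: dict[tuple[int, int], tuple] = {}
    for loop in range(0, max_loop + 1):
        for lstart in range(0, n - loop + 1):
            lend = lstart + loop
            # extend arms outward with the mismatch budget
            arm = 0
            mism: list[int] = []
            i, j = lstart - 1, lend
            while i >= 0 and j < n:
                if not is_wc(seq[i], seq[j]):
                    if len(mism) + 1 > max_mismatches:
                        break
                    mism.append(arm)
                arm += 1
                i -= 1
                j += 1
            # trim so the outer arm boundary is a Watson-Crick pair
            while arm > 0 and mism and mism[-1] == arm - 1:
                mism.pop()
                arm -= 1
            if arm == 0:
                continue
            # the inner boundary (adjacent to the loop) must also pair
            if mism and mism[0] == 0:
                continue
            span_len = 2 * arm + loop
            if span_len < min_total_length:
                continue
            start = lstart - arm
            end = lend + arm
            key = (start, end)
            rank = (len(mism), loop)
            if key not in best_by_span or rank < best_by_span[key][0]:
                best_by_span[key] = (rank, arm, loop, tuple(mism))
    # collapse: drop any candidate overlapped by a strictly longer one
    spans = sorted(best_by_span)
    kept = []
    for s, e in spans:
        length = e - s
        shadowed = any(
            (e2 - s2) > length and s2 < e and s < e2 for s2, e2 in spans
        )
        if not shadowed:
            kept.append((s, e))
    out = []
    for s, e in kept:
        _rank, arm, loop, mism = best_by_span[(s, e)]
        span_len = e - s
        pairing = [(k + 1, span_len - k) for k in range(arm)]
        # mism holds arm indices counted from the loop outward
        mismatch_positions = sorted(
            [arm - k for k in mism] + [arm + loop + 1 + k for k in mism]
        )
        dg = hairpin_dG(seq[s:e], pairing, model)
        out.append(
            Palindrome(
                sequence_id=sequence_id,
                start=s,
                end=e,
                arm_length=arm,
                loop_length=loop,
                pairing=pairing,
                mismatch_positions=mismatch_positions,
                delta_g=dg,
            )
        )
    out.sort(key=lambda p: (p.start, p.end))
    return out


# ---------------------------------------------------------------------------
# Templates and pairing profiles


@dataclasses.dataclass
class AlleleEdit:
    """One edit against a template: substitution or deletion, 1-based."""

    kind: str  # "sub" or "del"
    position: int
    to_base: str = ""  # for substitutions

    def __post_init__(self) -> None:
        if self.kind not in {"sub", "del"}:
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.kind == "sub" and self.to_base not in set("ACGT"):
            raise ValueError("substitution needs a target base")


@dataclasses.dataclass
class PalindromeTemplate:
    """A named near-palindromic locus with an explicit structural hypothesis.

    ``paired_position_map`` is the wild-type pairing (1-based); applying it to
    the wild-type sequence must yield Watson-Crick pairs only.  Named alleles
    are edit lists; an allele may carry its own pairing map when the mutation
    changes the structure (e.g. creates a new terminal pair).
    """

    name: str
    sequence: str
    paired_position_map: list[tuple[int, int]]
    named_alleles: dict[str, list[AlleleEdit]] = dataclasses.field(default_factory=dict)
    allele_pairing_maps: dict[str, list[tuple[int, int]]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence, context=self.name)
        for i, j in self.paired_position_map:
            if not (1 <= i < j <= len(self.sequence)):
                raise ValueError(f"{self.name}: pair ({i},{j}) out of range")
            if not is_wc(self.sequence[i - 1], self.sequence[j - 1]):
                raise ValueError(
                    f"{self.name}: wild-type pair ({i},{j}) is not Watson-Crick"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def allele_sequence(self, allele: str | None) -> str:
        """Apply a named allele's edits (positions refer to the wild type)."""
        if allele is None or allele == "wild_type":
            return self.sequence
        if allele not in self.named_alleles:
            raise KeyError(f"{self.name}: unknown allele {allele!r}")
        bases = list(self.sequence)
        deleted: set[int] = set()
        for edit in self.named_alleles[allele]:
            if edit.kind == "sub":
                bases[edit.position - 1] = edit.to_base
            else:
                deleted.add(edit.position - 1)
        return "".join(b for k, b in enumerate(bases) if k not in deleted)

    def pairing_map_for(self, allele: str | None) -> list[tuple[int, int]]:
        if allele in self.allele_pairing_maps:
            return self.allele_pairing_maps[allele]
        return self.paired_position_map


@dataclasses.dataclass
class PairingProfile:
    """Per-position pairing status over a palindromic span."""

    pairs: list[tuple[int, int, bool]]  # (i, j, watson_crick?) 1-based
    mismatch_positions: list[int]

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


def pairing_profile(
    obj: Palindrome | PalindromeTemplate,
    seq: str,
    allele: str | None = None,
) -> PairingProfile:
    """Pairing profile of a span under a structural hypothesis.

    For a detector :class:`Palindrome`, ``seq`` is the scanned sequence and
    the symmetric detection pairing is profiled; both members of a broken
    pair are reported as mismatch positions.  For a
    :class:`PalindromeTemplate`, ``seq`` is the observed span (wild type or an
    allele) profiled under the template map; a broken pair is reported at the
    member whose base deviates from the template wild type, which is how a
    single point mutation is localized to one position.
    """
    if isinstance(obj, Palindrome):
        if obj.end > len(seq):
            raise ValueError("palindrome span outside sequence")
        span = seq[obj.start : obj.end]
        pairs = []
        mism = []
        for i, j in obj.pairing:
            ok = is_wc(span[i - 1], span[j - 1])
            pairs.append((i, j, ok))
            if not ok:
                mism.extend([i, j])
        return PairingProfile(pairs, sorted(mism))
    template = obj
    observed = normalize_sequence(seq)
    pairing = template.pairing_map_for(allele)
    if len(observed) < max(j for _i, j in pairing):
        raise ValueError(
            f"{template.name}: observed span shorter than the pairing map"
        )
    pairs = []
    mism = []
    for i, j in pairing:
        ok = is_wc(observed[i - 1], observed[j - 1])
        pairs.append((i, j, ok))
        if not ok:
            dev_i = observed[i - 1] != template.sequence[i - 1]
            dev_j = observed[j - 1] != template.sequence[j - 1]
            if dev_i and not dev_j:
                mism.append(i)
            elif dev_j and not dev_i:
                mism.append(j)
            else:
                mism.extend([i, j])
    return PairingProfile(pairs, sorted(mism))


@dataclasses.dataclass
class AlleleComparison:
    allele_a: str
    allele_b: str
    span_a: int
    span_b: int
    delta_g_a: float
    delta_g_b: float
    pairing_deltas: list[tuple[int, int, bool, bool]]  # (i, j, wc_in_a, wc_in_b)
    classification: str


def compare_alleles(
    template: PalindromeTemplate,
    allele_a: str | None,
    allele_b: str | None,
    model: EnergyModel | None = None,
    tolerance: float = 0.1,
) -> AlleleComparison:
    """Side-by-side structural comparison of two alleles of a template.

    Spans are the maximal detected near-palindrome in each allele sequence;
    free energies come from each allele's structural hypothesis (the
    template map, or the allele-specific map when recorded).  ``allele_b`` is
    classified against ``allele_a`` as stabilizing/destabilizing/neutral by
    the free-energy change beyond ``tolerance`` kcal/mol.
    """
    model = model or default_energy_model()
    seq_a = template.allele_sequence(allele_a)
    seq_b = template.allele_sequence(allele_b)

    def max_span(s: str) -> int:
        found = find_palindromes(s, min_total_length=4, model=model)
        return max((p.total_length for p in found), default=0)

    dg_a = hairpin_dG(seq_a, template.pairing_map_for(allele_a), model)
    dg_b = hairpin_dG(seq_b, template.pairing_map_for(allele_b), model)
    prof_a = {
        (i, j): ok
        for i, j, ok in pairing_profile(template, seq_a, allele_a).pairs
    }
    prof_b = {
        (i, j): ok
        for i, j, ok in pairing_profile(template, seq_b, allele_b).pairs
    }
    deltas = []
    for key in sorted(set(prof_a) | set(prof_b)):
        deltas.append((key[0], key[1], prof_a.get(key, False), prof_b.get(key, False)))
    diff = dg_b - dg_a
    if diff < -tolerance:
        cls = "stabilizing"
    elif diff > tolerance:
        cls = "destabilizing"
    else:
        cls = "neutral"
    return AlleleComparison(
        allele_a=allele_a or "wild_type",
        allele_b=allele_b or "wild_type",
        span_a=max_span(seq_a),
        span_b=max_span(seq_b),
        delta_g_a=dg_a,
        delta_g_b=dg_b,
        pairing_deltas=deltas,
        classification=cls,
    )
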