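"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration or textbook
dynamic programming — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Global affine alignment score by plain DP (Gotoh, no vectorization)


def affine_global_score(x, y, match=2.0, mismatch=-3.0, open_=-6.0, extend=-1.0):
    NEG = float("-inf")
    n, m = len(x), len(y)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = open_ + extend * i
    for j in range(1, m + 1):
        I[0][j] = open_ + extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (x[i - 1] == y[j - 1] and x[i - 1] != "N") else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            D[i][j] = max(
                M[i - 1][j] + open_ + extend,
                D[i - 1][j] + extend,
                I[i - 1][j] + open_ + extend,
            )
            I[i][j] = max(
                M[i][j - 1] + open_ + extend,
                I[i][j - 1] + extend,
                D[i][j - 1] + open_ + extend,
            )
    return max(M[n][m], D[n][m], I[n][m])


# ---------------------------------------------------------------------------
# Near-palindrome enumeration over all (start, end, loop) triples


def _triple_valid(seq, start, end, loop, max_mismatches):
    span = end - start
    arm = (span - loop) // 2
    if arm < 1 or (span - loop) % 2:
        return None
    mism = []
    for k in range(arm):
        a, b = seq[start + k], seq[end - 1 - k]
        if (a, b) not in WC:
            mism.append(k)
    if len(mism) > max_mismatches:
        return None
    if mism and (0 in mism or (arm - 1) in mism):
        return None
    return tuple(mism)


def brute_palindrome_spans(seq, min_total_length=10, max_loop=4, max_mismatches=1):
    """All locally-longest near-palindrome spans by full enumeration.

    Returns a sorted list of (start, end) using the same selection rule the
    detector documents: a span survives unless a strictly longer valid span
    overlaps it.
    """
    n = len(seq)
    valid = set()
    for start in range(n):
        for end in range(start + min_total_length, n + 1):
            for loop in range(0, max_loop + 1):
                if _triple_valid(seq, start, end, loop, max_mismatches) is not None:
                    valid.add((start, end))
                    break
    kept = []
    for s, e in sorted(valid):
        if not any(
            (e2 - s2) > (e - s) and s2 < e and s < e2 for s2, e2 in valid
        ):
            kept.append((s, e))
    return kept


def brute_best_partition(seq, start, end, max_loop=4, max_mismatches=1):
    """(n_mismatches, loop) of the preferred partition for a fixed span."""
    best = None
    for loop in range(0, max_loop + 1):
        mism = _triple_valid(seq, start, end, loop, max_mismatches)
        if mism is None:
            continue
        rank = (len(mism), loop)
        if best is None or rank < best:
            best = rank
    return best


# ---------------------------------------------------------------------------
# Fitch parsimony by exhaustive ancestral labeling


def brute_fitch_min_changes(tree, states: dict[str, int]) -> int:
    """Minimum state changes over all labelings of the internal nodes.

    ``tree`` is a dendropy tree; ``states`` maps leaf labels to 0/1 (leaves
    absent from ``states`` are excluded).
    """
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [
        n for n in tree.leaf_node_iter() if n.taxon and n.taxon.label in states
    ]
    best = None
    for labels in itertools.product((0, 1), repeat=len(internal)):
        assign = dict(zip(internal, labels))
        changes = 0
        for node in internal:
            parent = node.parent_node
            if parent is not None and assign[parent] != assign[node]:
                changes += 1
        for leaf in leaves:
            state = states[leaf.taxon.label]
            if assign[leaf.parent_node] != state:
                changes += 1
        if best is None or changes < best:
            best = changes
    return best if best is not None else 0


# ---------------------------------------------------------------------------
# PWM window scoring


def brute_pwm_hits(seq, log_odds, threshold):
    """All above-threshold windows on both strands by direct scoring."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = len(log_odds[0])
    hits = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for start in range(len(s) - w + 1):
            window = s[start : start + w]
            if "N" in window:
                continue
            score = sum(log_odds[idx[b]][k] for k, b in enumerate(window))
            if score >= threshold:
                if strand == "+":
                    hits.append((start, start + w, "+", round(score, 6)))
                else:
                    hits.append((len(s) - start - w, len(s) - start, "-", round(score, 6)))
    return sorted(hits)


# ---------------------------------------------------------------------------
# Longest shared near-exact substring (TSD search)


def brute_tsd(a, b, min_len=8, max_mismatches=1):
    """Best (length, i, j) shared substring with internal-only mismatches."""
    best = None
    for i in range(len(a)):
        for j in range(len(b)):
            for k in range(min_len, min(len(a) - i, len(b) - j) + 1):
                mm = [
                    t
                    for t in range(k)
                    if a[i + t] != b[j + t] or a[i + t] == "N"
                ]
                if len(mm) > max_mismatches:
                    break
                if mm and (0 in mm or (k - 1) in mm):
                    continue
                cand = (k, -((len(a) - (i + k)) + j))
                if best is None or cand > best[0]:
                    best = (cand, i, j, k)
    if best is None:
        return None
    _key, i, j, k = best
    return k, i, j


# ---------------------------------------------------------------------------
# Single-linkage clustering of 1-D positions


def brute_single_linkage(positions, tolerance):
    """Clusters by repeated merging; returns sorted tuples of positions."""
    clusters = [[p] for p in positions]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    abs(p - q) <= tolerance
                    for p in clusters[i]
                    for q in clusters[j]
                ):
                    clusters[i] = clusters[i] + clusters[j]
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    return sorted(tuple(sorted(c)) for c in clusters)
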