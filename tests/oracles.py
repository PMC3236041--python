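"""Independent brute-force oracles used by the test suite.

Deliberately naive re-derivations, written against the definitions rather
than the package's code paths.
"""

from __future__ import annotations

import math

import numpy as np

NEG = float("-inf")


def brute_entropy(counts) -> float:
    """-sum p ln p, straight from the definition."""
    n = sum(counts)
    h = 0.0
    for c in counts:
        p = c / n
        h -= p * math.log(p)
    return h


def brute_broken_stick(S: int) -> list[float]:
    return [sum(1.0 / k for k in range(i, S + 1)) / S for i in range(1, S + 1)]


def brute_overrepresented(counts: dict[str, int]) -> list[str]:
    """Rank-by-rank comparison of sorted observed frequencies vs the
    broken-stick expectation; returns flagged category ids."""
    n = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    expected = brute_broken_stick(len(counts))
    return [cat for (cat, c), e in zip(ordered, expected) if c / n > e]


def sw_local_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Exhaustive affine-gap Smith-Waterman score (Gotoh three-state DP).

    A gap of length g costs gap_open + gap_extend * g; the empty alignment
    scores 0.
    """
    first_gap = gap_open + gap_extend
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]  # last column is a match/mismatch
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - first_gap, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - first_gap)
            Y[i][j] = max(M[i][j - 1] - first_gap, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - first_gap)
            if M[i][j] > best:
                best = M[i][j]
    return best


def _xdrop_extent(diff: np.ndarray, xdrop: int) -> int:
    """Offset of the running-maximum score along a +-1 score walk with the
    stop rule `running_max - score > xdrop`."""
    best = 0
    score = 0
    extent = 0
    for k, d in enumerate(diff, start=1):
        score += int(d)
        if score > best:
            best, extent = score, k
        elif best - score > xdrop:
            break
    return extent


def naive_hsps(sa: str, sb: str, word_size: int, xdrop: int, min_length: int):
    """All-pairs substring scan: every exact shared word is located by direct
    string comparison and extended via numpy score walks; containment on a
    diagonal is removed by pairwise comparison.  Returns a set of
    (a_start, a_end, b_start, b_end, identities) tuples."""
    sa, sb = sa.upper(), sb.upper()
    w = word_size
    segs = set()
    for i in range(len(sa) - w + 1):
        if "N" in sa[i : i + w]:
            continue
        for j in range(len(sb) - w + 1):
            if sa[i : i + w] != sb[j : j + w] or "N" in sb[j : j + w]:
                continue
            right_a = np.frombuffer(sa[i + w :].encode(), dtype="S1")
            right_b = np.frombuffer(sb[j + w :].encode(), dtype="S1")
            k = min(len(right_a), len(right_b))
            match = (right_a[:k] == right_b[:k]) & (right_a[:k] != b"N")
            right = _xdrop_extent(np.where(match, 1, -1), xdrop)
            left_a = np.frombuffer(sa[:i][::-1].encode(), dtype="S1")
            left_b = np.frombuffer(sb[:j][::-1].encode(), dtype="S1")
            k = min(len(left_a), len(left_b))
            match = (left_a[:k] == left_b[:k]) & (left_a[:k] != b"N")
            left = _xdrop_extent(np.where(match, 1, -1), xdrop)
            segs.add((i - left, i + w + right, j - left, j + w + right))
    # drop segments contained in another segment on the same diagonal
    kept = []
    for s in segs:
        contained = any(
            t != s
            and t[2] - t[0] == s[2] - s[0]  # same diagonal
            and t[0] <= s[0]
            and s[1] <= t[1]
            for t in segs
        )
        if not contained and s[1] - s[0] >= min_length:
            kept.append(s)
    out = set()
    for a0, a1, b0, b1 in kept:
        ident = sum(
            1 for k in range(a1 - a0) if sa[a0 + k] == sb[b0 + k] and sa[a0 + k] != "N"
        )
        out.add((a0, a1, b0, b1, ident))
    return out


def longest_common_substring(a: str, b: str) -> int:
    """Classic O(nm) DP."""
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    best = 0
    bb = np.frombuffer(b.encode(), dtype="S1")
    for ch in a:
        cur = np.zeros(len(b) + 1, dtype=np.int32)
        hits = bb == ch.encode()
        cur[1:][hits] = prev[:-1][hits] + 1
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best
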