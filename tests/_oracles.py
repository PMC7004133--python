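"""Independent reference implementations used only to check the package.

These deliberately share no code with tedyn: a plain-Python Gotoh DP and a
full alignment-path enumeration for affine-gap global alignment, a direct
closed-form K2P evaluator, and brute-force interval helpers.
"""

from __future__ import annotations

import math
from functools import lru_cache

NEG = float("-inf")


def gotoh_score(a: str, b: str, match=2.0, mismatch=-3.0, gap_open=5.0, gap_extend=2.0) -> float:
    """Affine-gap global alignment score; gap of length L costs open + extend*L."""
    n, m = len(a), len(b)
    go = gap_open + gap_extend
    ge = gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + ge * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + ge * j)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = match if a[i - 1] == b[j - 1] else mismatch
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if i > 0 and not (i > 0 and j == 0):
                X[i][j] = max(
                    X[i][j],
                    M[i - 1][j] - go,
                    X[i - 1][j] - ge,
                    Y[i - 1][j] - go,
                )
            if j > 0 and not (j > 0 and i == 0):
                Y[i][j] = max(
                    Y[i][j],
                    M[i][j - 1] - go,
                    Y[i][j - 1] - ge,
                    X[i][j - 1] - go,
                )
    return max(M[n][m], X[n][m], Y[n][m])


def enumerate_score(a: str, b: str, match=2.0, mismatch=-3.0, gap_open=5.0, gap_extend=2.0) -> float:
    """Best score over ALL global alignments, by explicit path enumeration."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        out = NEG
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            out = max(out, s + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open + gap_extend
            out = max(out, -cost + best(i + 1, j, "X"))
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open + gap_extend
            out = max(out, -cost + best(i, j + 1, "Y"))
        return out

    return best(0, 0, "M")


def k2p_closed_form(P: float, Q: float) -> float:
    """Direct evaluation of K = -1/2 ln((1-2P-Q) sqrt(1-2Q))."""
    return -0.5 * math.log((1.0 - 2.0 * P - Q) * math.sqrt(1.0 - 2.0 * Q))


def intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return min(a[1], b[1]) - max(a[0], b[0]) > 0


def one_way_80(a: tuple[int, int], b: tuple[int, int]) -> bool:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return False
    return ov >= 0.8 * (a[1] - a[0]) or ov >= 0.8 * (b[1] - b[0])


def per_base_coverage(span: tuple[int, int], intervals: list[tuple[int, int]]) -> float:
    """TE coverage of a span computed base by base (no interval arithmetic)."""
    s, e = span
    if e <= s:
        return 0.0
    covered = 0
    for pos in range(s, e):
        if any(lo <= pos < hi for lo, hi in intervals):
            covered += 1
    return covered / (e - s)
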