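"""Independent brute-force oracles used by the test suite.

These are deliberately naive quadratic dynamic programs and exhaustive
enumerations, kept separate from the package implementation so the two
can disagree.
"""

from __future__ import annotations

import math


def lcs_dp(a: str, b: str) -> int:
    """Textbook O(mn) longest-common-subsequence recurrence."""
    m, n = len(a), len(b)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[n]


def edit_dp(a: str, b: str) -> int:
    """Textbook Levenshtein recurrence."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[n]


def infix_edit_dp(a: str, b: str) -> int:
    """Minimum edit distance of ``a`` against any substring of ``b``."""
    m, n = len(a), len(b)
    prev = [0] * (n + 1)  # first row free: a may start anywhere in b
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def _col_dist(v, w) -> int:
    d = math.sqrt(sum((x - y) ** 2 for x, y in zip(v, w)))
    return int(math.floor(d / math.sqrt(200.0) * 255.0 + 0.5))


def _col_weight(v, w) -> int:
    return max(0, min(10, 20 - (v[4] + w[4])))


GAP_COL = (0, 0, 0, 0, 10)


def profile_dp(cols_a, cols_b):
    """Unbanded weighted-distance profile alignment.

    Global DP minimizing sum(distance * weight), gaps paired with the
    all-gap column; among equal-cost predecessors the larger accumulated
    weight wins.  Returns (wd, weight_sum).
    """
    k1, k2 = len(cols_a), len(cols_b)
    gc_a = [_col_dist(c, GAP_COL) * _col_weight(c, GAP_COL) for c in cols_a]
    gw_a = [_col_weight(c, GAP_COL) for c in cols_a]
    gc_b = [_col_dist(c, GAP_COL) * _col_weight(c, GAP_COL) for c in cols_b]
    gw_b = [_col_weight(c, GAP_COL) for c in cols_b]
    F = [[0] * (k2 + 1) for _ in range(k1 + 1)]
    W = [[0] * (k2 + 1) for _ in range(k1 + 1)]
    for j in range(1, k2 + 1):
        F[0][j] = F[0][j - 1] + gc_b[j - 1]
        W[0][j] = W[0][j - 1] + gw_b[j - 1]
    for i in range(1, k1 + 1):
        F[i][0] = F[i - 1][0] + gc_a[i - 1]
        W[i][0] = W[i - 1][0] + gw_a[i - 1]
        for j in range(1, k2 + 1):
            cands = [
                (F[i - 1][j - 1] + _col_dist(cols_a[i - 1], cols_b[j - 1])
                 * _col_weight(cols_a[i - 1], cols_b[j - 1]),
                 W[i - 1][j - 1] + _col_weight(cols_a[i - 1], cols_b[j - 1])),
                (F[i - 1][j] + gc_a[i - 1], W[i - 1][j] + gw_a[i - 1]),
                (F[i][j - 1] + gc_b[j - 1], W[i][j - 1] + gw_b[j - 1]),
            ]
            fmin = min(f for f, _ in cands)
            F[i][j] = fmin
            W[i][j] = max(w for f, w in cands if f == fmin)
    return F[k1][k2], W[k1][k2]


def profile_ws(wd: int, wsum: int) -> float:
    if wsum == 0:
        return 100.0
    return 100.0 - wd / (255.0 * wsum) * 100.0
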