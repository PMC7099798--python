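"""Independent brute-force oracles used across the suite.

Everything here is deliberately naive — enumeration, literal definitions,
nested loops — and shares no code path with the package.
"""

from __future__ import annotations

import itertools
from math import comb, sqrt

import numpy as np


def hypergeom_upper_tail_enum(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) by summing the hypergeometric pmf written out with comb()."""
    total = comb(N, n)
    acc = 0
    for k in range(x, min(K, n) + 1):
        if n - k <= N - K:
            acc += comb(K, k) * comb(N - K, n - k)
    return acc / total


def fisher_twosided_enum(table) -> float:
    """Two-sided Fisher p by enumerating every table with the fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def point_prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(N, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = point_prob(a)
    return sum(
        point_prob(x) for x in range(lo, hi + 1)
        if point_prob(x) <= p_obs * (1 + 1e-7)
    )


def bh_bruteforce(pvalues) -> np.ndarray:
    """BH step-up from the literal definition: suffix minima of m*p_(j)/j."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / (np.arange(m) + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def pearson_manual(x, y) -> float:
    """Textbook covariance / (sigma_x * sigma_y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / sqrt((xm**2).sum() * (ym**2).sum()))


def window_starts_enum(length: int, step: int) -> list[int]:
    """All window starts 0, s, 2s, ... strictly below the chromosome length."""
    return [s for s in itertools.takewhile(lambda v: v < length, itertools.count(0, step))]


def median_polish_by_hand(matrix, n_sweeps: int = 10):
    """Literal alternating row/column median sweeps; returns summarized columns."""
    r = np.array(matrix, dtype=float)
    overall = 0.0
    row = np.zeros(r.shape[0])
    col = np.zeros(r.shape[1])
    for _ in range(n_sweeps):
        rm = np.median(r, axis=1)
        row += rm
        r -= rm[:, None]
        overall += np.median(row)
        row -= np.median(row)
        cm = np.median(r, axis=0)
        col += cm
        r -= cm[None, :]
        overall += np.median(col)
        col -= np.median(col)
    return overall + col
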