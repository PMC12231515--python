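"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — enumeration, closed forms, direct
distance scans — and shares no code with the package internals it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def chebyshev_distance_map(section: np.ndarray) -> np.ndarray:
    """Exact in-plane Chebyshev distance from every pixel to the mask.

    Direct O(n^2) scan over pixel pairs; fine for small frames.
    """
    h, w = section.shape
    ys, xs = np.nonzero(section)
    dist = np.full((h, w), np.inf)
    for y in range(h):
        for x in range(w):
            d = np.max(np.abs(np.stack([ys - y, xs - x])), axis=0).min()
            dist[y, x] = d
    return dist


def ring_pixel_count(section: np.ndarray, d_lo: int = 2, d_hi: int = 3) -> int:
    dist = chebyshev_distance_map(section)
    return int(((dist >= d_lo) & (dist <= d_hi)).sum())


def dice_by_counting(a: np.ndarray, b: np.ndarray) -> float:
    """Dice via explicit voxel iteration (no vectorized set ops)."""
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    inter = sum(1 for x, y in zip(a, b) if x and y)
    na = sum(1 for x in a if x)
    nb = sum(1 for y in b if y)
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def rank_with_midranks(values: np.ndarray) -> np.ndarray:
    """Midrank assignment by sorting, independent of scipy.rankdata."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def wilcoxon_exact_by_enumeration(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns.

    Zero differences are dropped; midranks for tied |d|.  Returns
    (W+, p).  Intended for n <= ~12.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = rank_with_midranks(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return w_obs, count / 2**n


def spearman_closed_form(x: np.ndarray, y: np.ndarray) -> float:
    """rho = 1 - 6 sum(d^2) / (n (n^2 - 1)); valid only for tie-free data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rx = rank_with_midranks(x)
    ry = rank_with_midranks(y)
    d2 = ((rx - ry) ** 2).sum()
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def nearest_rank_percentile(sorted_values, p: float):
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    import math

    n = len(sorted_values)
    r = max(1, math.ceil(p / 100.0 * n))
    return sorted_values[r - 1]
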