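"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit Python loops and elementary
formulas, deliberately sharing no code with the package, so agreement
between the two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def naive_distance_matrix(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    n = m.shape[0]
    d = np.zeros((n, n))
    for k in range(n):
        for l in range(n):
            d[k, l] = math.dist(m[k], m[l])
    return d


def naive_double_center(d) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    row = [sum(d[k, l] for l in range(n)) / n for k in range(n)]
    col = [sum(d[k, l] for k in range(n)) / n for l in range(n)]
    grand = sum(d[k, l] for k in range(n) for l in range(n)) / n**2
    c = np.zeros_like(d)
    for k in range(n):
        for l in range(n):
            c[k, l] = d[k, l] - row[k] - col[l] + grand
    return c


def naive_dcov2(x, y) -> float:
    """(1/n^2) sum_kl A_kl B_kl via explicit loops over both matrices."""
    a = naive_double_center(naive_distance_matrix(x))
    b = naive_double_center(naive_distance_matrix(y))
    n = a.shape[0]
    total = 0.0
    for k in range(n):
        for l in range(n):
            total += a[k, l] * b[k, l]
    return total / n**2


def naive_dcor(x, y) -> float:
    vxy = naive_dcov2(x, y)
    vxx = naive_dcov2(x, x)
    vyy = naive_dcov2(y, y)
    if vxx * vyy <= 0:
        return 0.0
    return math.sqrt(max(vxy, 0.0) / math.sqrt(vxx * vyy))


def brute_force_inner_edge(coords, labels, cell_type, k):
    """Inner/edge split using an independent k-nearest-neighbor search.

    Ties at equal distance are broken toward the smaller index, matching
    the documented graph convention. Returns (inner, edge) index lists.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    inner, edge = [], []
    for i in range(n):
        if labels[i] != cell_type:
            continue
        cand = sorted(
            (math.dist(coords[i], coords[j]), j)
            for j in range(n)
            if j != i
        )
        nb = [j for _, j in cand[:k]]
        if all(labels[j] == cell_type for j in nb):
            inner.append(i)
        else:
            edge.append(i)
    return inner, edge
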