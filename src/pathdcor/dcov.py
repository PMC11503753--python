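"""Empirical Brownian distance covariance / correlation and its permutation test.

The statistic is the V-statistic (biased) estimator: with a and b the
pairwise Euclidean distance matrices of the two samples and A, B their
double-centered versions,

    V_n^2(X, Y) = (1/n^2) sum_{k,l} A_kl B_kl
    R_n^2(X, Y) = V_n^2(X, Y) / sqrt(V_n^2(X) V_n^2(Y))   (0 if denominator 0)

and the reported dCor is the square root R_n in [0, 1]. The permutation
null shuffles sample labels on one side only; because double centering
commutes with a simultaneous row/column permutation, each permuted
statistic is computed by conjugating the permuted side's centered matrix —
the fixed side's centered matrix and both self-dCov terms are computed
once. Computation is O(n^2) time and memory per evaluation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import DataError, DcorResult

# Negative V_n^2 can only arise from float cancellation; anything bigger
# than this (relative to the statistic's scale) signals a bug.
_NEG_CLAMP_REL = 1e-12


def pairwise_distances(m: np.ndarray) -> np.ndarray:
    """Symmetric n x n Euclidean distance matrix of the rows of ``m``."""
    m = np.asarray(m, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    if m.ndim != 2:
        raise DataError("sample must be an n x p matrix")
    if m.shape[0] < 2:
        raise DataError("need at least 2 samples for distances")
    if not np.all(np.isfinite(m)):
        raise DataError("non-finite values in sample")
    return squareform(pdist(m))


def double_center(d: np.ndarray) -> np.ndarray:
    """A_kl = a_kl - rowmean_k - colmean_l + grandmean."""
    d = np.asarray(d, dtype=float)
    row = d.mean(axis=1, keepdims=True)
    col = d.mean(axis=0, keepdims=True)
    return d - row - col + d.mean()


def dcov2(a_centered: np.ndarray, b_centered: np.ndarray) -> float:
    """(1/n^2) sum A_kl B_kl, clamped to >= 0.

    A negative value beyond float-cancellation magnitude raises, because
    the V-statistic is nonnegative by construction.
    """
    a_centered = np.asarray(a_centered, dtype=float)
    b_centered = np.asarray(b_centered, dtype=float)
    if a_centered.shape != b_centered.shape:
        raise DataError(
            f"centered matrices differ in shape: "
            f"{a_centered.shape} vs {b_centered.shape}"
        )
    v = float((a_centered * b_centered).mean())
    if v < 0:
        scale = float(np.abs(a_centered * b_centered).mean()) + np.finfo(float).tiny
        if -v > _NEG_CLAMP_REL * scale:
            raise DataError(
                f"distance covariance {v} is negative beyond rounding error"
            )
        v = 0.0
    return v


def _dcor_from_parts(vxy: float, vxx: float, vyy: float) -> float:
    denom2 = vxx * vyy
    if denom2 <= 0:
        return 0.0
    r2 = vxy / np.sqrt(denom2)
    # r2 in [0, 1] up to rounding by Cauchy-Schwarz
    return float(np.sqrt(min(max(r2, 0.0), 1.0)))


def dcor(x: np.ndarray, y: np.ndarray) -> DcorResult:
    """Distance correlation between two samples (rows are observations)."""
    a = double_center(pairwise_distances(x))
    b = double_center(pairwise_distances(y))
    if a.shape != b.shape:
        raise DataError(
            f"samples differ in size: n={a.shape[0]} vs n={b.shape[0]}"
        )
    vxy = dcov2(a, b)
    vxx = dcov2(a, a)
    vyy = dcov2(b, b)
    return DcorResult(
        dcov2=vxy, dcor=_dcor_from_parts(vxy, vxx, vyy), n=a.shape[0]
    )


def permutation_indices(
    n: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw a ``(n_permutations, n)`` block of permutations from ``rng``.

    A screen that shares one block across all pathways makes their p-values
    directly comparable and the ranking independent of test order.
    """
    return np.array([rng.permutation(n) for _ in range(n_permutations)])


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    permutations: Optional[np.ndarray] = None,
    permute_side: str = "X",
) -> DcorResult:
    """Permutation p-value for dCor(x, y).

    One side's sample labels are shuffled (default ``X``, the expression
    side) while the other stays fixed. The p-value uses the add-one
    convention p = (1 + #{permuted >= observed}) / (1 + B), which keeps
    p > 0 and attains the floor 1/(B+1); ties count as exceedances.
    ``permutations`` may supply a precomputed index block (see
    :func:`permutation_indices`), overriding ``seed``/``rng``.
    """
    if n_permutations < 1:
        raise DataError("need at least one permutation")
    if permute_side not in ("X", "Y"):
        raise DataError("permute_side must be 'X' or 'Y'")

    a = double_center(pairwise_distances(x))
    b = double_center(pairwise_distances(y))
    if a.shape != b.shape:
        raise DataError(
            f"samples differ in size: n={a.shape[0]} vs n={b.shape[0]}"
        )
    n = a.shape[0]
    vxy = dcov2(a, b)
    vxx = dcov2(a, a)
    vyy = dcov2(b, b)
    observed = _dcor_from_parts(vxy, vxx, vyy)

    if permutations is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        permutations = permutation_indices(n, n_permutations, rng)
    else:
        permutations = np.asarray(permutations)
        if permutations.shape != (n_permutations, n):
            raise DataError(
                f"permutation block has shape {permutations.shape}, "
                f"expected {(n_permutations, n)}"
            )

    moving, fixed = (a, b) if permute_side == "X" else (b, a)
    exceed = 0
    for idx in permutations:
        # conjugation: centered matrix of the permuted sample, exactly
        perm_num = float((moving[np.ix_(idx, idx)] * fixed).mean())
        stat = _dcor_from_parts(max(perm_num, 0.0), vxx, vyy)
        if stat >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return DcorResult(
        dcov2=vxy,
        dcor=observed,
        n=n,
        n_permutations=n_permutations,
        p_value=p,
        seed=seed,
    )
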