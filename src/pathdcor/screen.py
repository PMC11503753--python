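"""The unsupervised pathway screen: every gene set against spot coordinates.

Each set's expression submatrix X (spots x genes, normalized log layer) is
tested against the coordinates Y with the distance-correlation permutation
test, expression side shuffled. Multiple-testing columns: Benjamini-
Hochberg q-values always, and an empirical-Bayes local FDR when enough
sets were tested for the density fit to be stable. A Cauchy (ACAT-style)
combination of per-gene p-values is provided for gene-level baselines.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import dcov
from .containers import (
    CoordinateMatrix,
    DataError,
    DcorResult,
    ExpressionMatrix,
    GeneSetCollection,
    NORMALIZED_LOG,
    align_spots,
)
from .preprocess import (
    PreprocessConfig,
    extract_pathway_submatrix,
    filter_genes_by_min_cells,
    filter_sets_by_size,
    normalize_and_log,
)

RESULT_COLUMNS = [
    "set_id",
    "description",
    "n_genes_annotated",
    "n_genes_used",
    "dcov2",
    "dcor",
    "p_value",
    "q_value_bh",
    "local_fdr",
]


@dataclass
class ScreenConfig:
    n_permutations: int = 10_000
    seed: int = 0
    share_permutations: bool = True
    adjust: tuple[str, ...] = ("bh", "local_fdr")

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise DataError("n_permutations must be >= 1")
        unknown = set(self.adjust) - {"bh", "local_fdr"}
        if unknown:
            raise DataError(f"unknown adjustment(s): {sorted(unknown)}")


@dataclass
class CombinationResult:
    """Cauchy combination statistic T and the aggregated p-value."""

    T: float
    p_pathway: float


def test_pathway_location(
    expr_sub: ExpressionMatrix,
    coords: CoordinateMatrix,
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    permutations: Optional[np.ndarray] = None,
) -> DcorResult:
    """Permutation dCor test of one pathway submatrix against coordinates.

    A single-gene submatrix is the per-gene special case of the same test.
    """
    if expr_sub.layer != NORMALIZED_LOG:
        raise DataError(
            "pathway testing requires the normalized_log layer; "
            "normalize raw counts first"
        )
    if expr_sub.n_genes < 1:
        raise DataError("pathway submatrix has no genes")
    coords, _ = align_spots(expr_sub, coords)
    return dcov.permutation_test(
        expr_sub.values,
        coords.coords,
        n_permutations=n_permutations,
        seed=seed,
        rng=rng,
        permutations=permutations,
        permute_side="X",
    )


def run_pathway_screen(
    expr: ExpressionMatrix,
    coords: CoordinateMatrix,
    sets: GeneSetCollection,
    preprocess_cfg: Optional[PreprocessConfig] = None,
    screen_cfg: Optional[ScreenConfig] = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Test every (size-filtered) gene set against the coordinates.

    Raw-count input is detection-filtered and normalized first; input
    already on the normalized_log layer is used as-is. Returns the results
    table sorted by descending dCor plus a list of skipped sets (too few
    measured genes) for a sidecar log.
    """
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    screen_cfg = screen_cfg or ScreenConfig()

    if expr.layer != NORMALIZED_LOG:
        expr = filter_genes_by_min_cells(expr, preprocess_cfg.min_cells)
        expr = normalize_and_log(expr, preprocess_cfg.target_sum)
    coords, _ = align_spots(expr, coords)

    sets = filter_sets_by_size(
        sets, preprocess_cfg.set_size_min, preprocess_cfg.set_size_max
    )

    shared = None
    if screen_cfg.share_permutations:
        rng = np.random.default_rng(screen_cfg.seed)
        shared = dcov.permutation_indices(
            expr.n_spots, screen_cfg.n_permutations, rng
        )

    rows: list[dict] = []
    skipped: list[dict] = []
    for set_id in sets.set_ids:
        sub = extract_pathway_submatrix(
            expr, set_id, sets, preprocess_cfg.min_genes_used
        )
        if sub.skipped:
            skipped.append(
                {
                    "set_id": set_id,
                    "n_genes_annotated": sub.n_genes_annotated,
                    "n_genes_used": sub.n_genes_used,
                    "reason": f"fewer than {preprocess_cfg.min_genes_used} measured genes",
                }
            )
            continue
        if shared is not None:
            res = test_pathway_location(
                sub.expr, coords,
                n_permutations=screen_cfg.n_permutations,
                permutations=shared,
            )
        else:
            res = test_pathway_location(
                sub.expr, coords,
                n_permutations=screen_cfg.n_permutations,
                rng=np.random.default_rng(
                    (screen_cfg.seed, zlib.crc32(set_id.encode()))
                ),
            )
        rows.append(
            {
                "set_id": set_id,
                "description": sets[set_id].description,
                "n_genes_annotated": sub.n_genes_annotated,
                "n_genes_used": sub.n_genes_used,
                "dcov2": res.dcov2,
                "dcor": res.dcor,
                "p_value": res.p_value,
            }
        )

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS[:7])
    if len(table):
        if "bh" in screen_cfg.adjust:
            table["q_value_bh"] = bh_adjust(table["p_value"].to_numpy())
        else:
            table["q_value_bh"] = np.nan
        if "local_fdr" in screen_cfg.adjust:
            fdr = local_fdr(
                table["p_value"].to_numpy(),
                p_floor=1.0 / (screen_cfg.n_permutations + 1),
            )
            table["local_fdr"] = np.nan if fdr is None else fdr
        else:
            table["local_fdr"] = np.nan
        table = table.sort_values(
            ["dcor", "set_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table = pd.DataFrame(columns=RESULT_COLUMNS)
    return table, skipped


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order matching the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def local_fdr(
    p_values: Sequence[float],
    p_floor: float = 1e-8,
    min_tests: int = 50,
    poly_degree: int = 7,
    n_bins: int = 71,
) -> Optional[np.ndarray]:
    """Empirical-Bayes local false discovery rate on probit-transformed p.

    Two-group model with a theoretical N(0, 1) null on z = Phi^-1(1 - p):
    the marginal density f(z) is fitted by Lindsey's method (Poisson
    regression of histogram counts on a polynomial basis), the null
    proportion pi0 by central matching, and fdr(z) = pi0 f0(z) / f(z)
    clipped to [0, 1]. Returns None (with a warning) for fewer than
    ``min_tests`` p-values, where the density fit is unstable. Permutation
    p-values are clipped to [p_floor, 1 - p_floor] before the transform.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < min_tests:
        warnings.warn(
            f"local FDR skipped: needs >= {min_tests} tests, got {p.size}",
            stacklevel=2,
        )
        return None
    if np.all(p == p[0]):
        raise DataError("local FDR undefined: all p-values identical")
    z = stats.norm.isf(np.clip(p, p_floor, 1 - p_floor))

    lo, hi = z.min() - 0.1, z.max() + 0.1
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    # Lindsey's method: Poisson GLM of counts on a standardized poly basis
    t = (mids - mids.mean()) / mids.std()
    design = np.vander(t, poly_degree + 1, increasing=True)
    fit = sm.GLM(counts, design, family=sm.families.Poisson()).fit()
    f_mid = fit.mu / (p.size * width)  # fitted marginal density at bin mids

    f0_mid = stats.norm.pdf(mids)
    central = np.abs(mids) <= 1.0
    if not central.any():
        central = np.argsort(np.abs(mids))[:5]
    ratio = f_mid[central] / np.maximum(f0_mid[central], 1e-300)
    pi0 = float(np.clip(np.median(ratio), 1e-6, 1.0))

    log_f = np.log(np.maximum(f_mid, 1e-300))
    f_z = np.exp(np.interp(z, mids, log_f))
    fdr = pi0 * stats.norm.pdf(z) / np.maximum(f_z, 1e-300)
    return np.clip(fdr, 0.0, 1.0)


def cauchy_combine(p_values: Sequence[float]) -> CombinationResult:
    """Cauchy combination (ACAT): T = mean tan(pi (0.5 - p_i)).

    The aggregated p-value is the standard Cauchy upper tail 1 - F(T) =
    0.5 - arctan(T)/pi; inputs are clipped to [1e-15, 1 - 1e-15] so the
    tangent stays finite. For a single p the transform is an involution
    and the aggregate equals the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise DataError("cauchy_combine needs at least one p-value")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    p = np.clip(p, 1e-15, 1 - 1e-15)
    T = float(np.tan(np.pi * (0.5 - p)).mean())
    return CombinationResult(T=T, p_pathway=float(stats.cauchy.sf(T)))
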