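"""Synthetic spatial transcriptomics with known spatially-variable pathways.

The generator lays spots on a unit square grid with a central "cancer"
disk covering a quarter of the spots, mimicking the elevated-expression
tumor core of a PDAC section. Of 3000 genes, half are spatially variable
(SVG) and half are not. Non-SVG expression is i.i.d. Normal(1, 1). Each
SVG mixes two components:

    expression = scale * expression_st + (1 - scale) * expression_rand

where expression_st is a multivariate normal over spots whose mean is
region-structured (cancer spots share a mean drawn U(2, 5), other spots
U(0, 2)) with a random covariance (off-diagonal U(0, 1), unit diagonal,
repaired to positive semidefinite), expression_rand is i.i.d. U(1, 5),
and scale ~ U(0.1, 0.2) keeps each single gene's pattern weak. Twenty
pathways of one hundred genes each mix fifty SVG with fifty non-SVG
genes. A pure-null generator (every gene Normal(1, 1), no spatial
structure) supports type-I-error calibration.

Simulated expression is emitted on the normalized_log layer: the
generator's values are already on an arbitrary continuous scale, so the
screen's count normalization does not apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .containers import (
    CoordinateMatrix,
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    NORMALIZED_LOG,
)


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the study conditions."""

    n_spots: int = 900  # 30 x 30 grid
    layout: str = "grid_blob"  # or "mask_file"
    cancer_fraction: float = 0.25
    n_genes: int = 3000
    svg_fraction: float = 0.5
    scale_min: float = 0.1
    scale_max: float = 0.2
    cancer_mean_range: tuple[float, float] = (2.0, 5.0)
    other_mean_range: tuple[float, float] = (0.0, 2.0)
    rand_range: tuple[float, float] = (1.0, 5.0)
    nonsvg_mean: float = 1.0
    nonsvg_sd: float = 1.0
    n_pathways: int = 20
    genes_per_pathway: int = 100
    svg_per_pathway: int = 50
    per_gene_covariance: bool = False
    seed: int = 0
    mask: Optional[np.ndarray] = None  # required for layout="mask_file"

    def __post_init__(self) -> None:
        if not (0 <= self.scale_min <= self.scale_max <= 1):
            raise DataError("need 0 <= scale_min <= scale_max <= 1")
        if self.svg_per_pathway > self.genes_per_pathway:
            raise DataError("svg_per_pathway must be <= genes_per_pathway")
        if not (0 < self.cancer_fraction < 1):
            raise DataError("cancer_fraction must be in (0, 1)")
        if self.layout not in ("grid_blob", "mask_file"):
            raise DataError("layout must be 'grid_blob' or 'mask_file'")


@dataclass
class SimulatedDataset:
    expr: ExpressionMatrix
    coords: CoordinateMatrix
    cancer_mask: np.ndarray  # per-spot bool
    svg_flags: dict[str, bool]  # gene id -> is SVG
    scales: dict[str, float]  # gene id -> mixing scale (0.0 for non-SVG)
    sets: GeneSetCollection
    config: SimulationConfig


def make_spatial_layout(
    config: SimulationConfig,
) -> tuple[CoordinateMatrix, np.ndarray]:
    """Unit-spaced square grid with a central disk as the cancer region.

    The disk is the smallest-radius one (centered at the grid center)
    holding at least ``cancer_fraction`` of the spots, ties broken toward
    the smaller spot index. ``mask_file`` layouts pass the mask through.
    """
    if config.layout == "mask_file":
        if config.mask is None:
            raise DataError("mask_file layout needs a mask")
        mask = np.asarray(config.mask, dtype=bool)
        if mask.size != config.n_spots:
            raise DataError("mask length does not match n_spots")
        coords = _grid_coords(config.n_spots)
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise DataError("need >= 2 spots in each region")
        return coords, mask

    coords = _grid_coords(config.n_spots)
    xy = coords.coords
    center = xy.mean(axis=0)
    dist = np.sqrt(((xy - center) ** 2).sum(axis=1))
    n = config.n_spots
    n_cancer = math.ceil(config.cancer_fraction * n)
    if n_cancer < 2 or n - n_cancer < 2:
        raise DataError(
            f"cancer_fraction={config.cancer_fraction} leaves fewer than "
            f"2 spots in one region"
        )
    order = np.lexsort((np.arange(n), dist))
    mask = np.zeros(n, dtype=bool)
    mask[order[:n_cancer]] = True
    return coords, mask


def _grid_coords(n_spots: int) -> CoordinateMatrix:
    side = math.isqrt(n_spots)
    if side * side != n_spots:
        raise DataError(
            f"grid layout needs a square spot count, got {n_spots}"
        )
    ii, jj = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    xy = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    ids = [f"spot_{i:05d}" for i in range(n_spots)]
    return CoordinateMatrix(xy, ids)


def sample_nonsvg(
    n_spots: int,
    n_genes_nonsvg: int,
    rng: np.random.Generator,
    mean: float = 1.0,
    sd: float = 1.0,
) -> np.ndarray:
    """i.i.d. Normal(mean, sd) expression, spots x genes."""
    return rng.normal(mean, sd, size=(n_spots, n_genes_nonsvg))


def spot_covariance_factor(n: int, rng: np.random.Generator) -> np.ndarray:
    """Factor L with L L^T = the repaired random spot covariance.

    The raw matrix (symmetric off-diagonal U(0, 1), unit diagonal) is
    generally indefinite; eigenvalues are clipped at 1e-8 and the diagonal
    renormalized to 1, which preserves positive semidefiniteness.
    """
    m = rng.uniform(0.0, 1.0, size=(n, n))
    s = 0.5 * (m + m.T)
    np.fill_diagonal(s, 1.0)
    w, v = np.linalg.eigh(s)
    if not np.all(np.isfinite(w)):
        raise DataError("covariance eigendecomposition failed")
    w = np.clip(w, 1e-8, None)
    repaired_diag = (v * v * w).sum(axis=1)
    scale = 1.0 / np.sqrt(repaired_diag)
    return (v * np.sqrt(w)) * scale[:, None]


def sample_svg(
    coords: CoordinateMatrix,
    cancer_mask: np.ndarray,
    n_svg: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    cov_factor: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """SVG expression (spots x n_svg) and per-gene mixing scales."""
    n = coords.n_spots
    mask = np.asarray(cancer_mask, dtype=bool)
    if mask.size != n:
        raise DataError("mask length does not match coordinates")
    if cov_factor is None:
        cov_factor = spot_covariance_factor(n, rng)
    mu_c = rng.uniform(*config.cancer_mean_range, size=n_svg)
    mu_o = rng.uniform(*config.other_mean_range, size=n_svg)
    mu = np.where(mask[:, None], mu_c[None, :], mu_o[None, :])
    if config.per_gene_covariance:
        st = np.empty((n, n_svg))
        for g in range(n_svg):
            lg = spot_covariance_factor(n, rng)
            st[:, g] = mu[:, g] + lg @ rng.standard_normal(n)
    else:
        st = mu + cov_factor @ rng.standard_normal((n, n_svg))
    rand = rng.uniform(*config.rand_range, size=(n, n_svg))
    scales = rng.uniform(config.scale_min, config.scale_max, size=n_svg)
    return scales * st + (1.0 - scales) * rand, scales


def build_simulated_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Assemble expression, coordinates, ground truth, and pathways."""
    rng = np.random.default_rng(config.seed)
    coords, mask = make_spatial_layout(config)

    n_svg = round(config.n_genes * config.svg_fraction)
    n_non = config.n_genes - n_svg
    need_svg = config.n_pathways * config.svg_per_pathway
    need_non = config.n_pathways * (config.genes_per_pathway - config.svg_per_pathway)
    if need_svg > n_svg or need_non > n_non:
        raise DataError(
            f"gene pools too small: pathways need {need_svg} SVG / "
            f"{need_non} non-SVG, pools hold {n_svg} / {n_non}"
        )

    svg_values, svg_scales = sample_svg(coords, mask, n_svg, config, rng)
    non_values = sample_nonsvg(
        coords.n_spots, n_non, rng, config.nonsvg_mean, config.nonsvg_sd
    )

    gene_ids = [f"gene_{i:05d}" for i in range(config.n_genes)]
    flags = np.concatenate(
        [np.ones(n_svg, dtype=bool), np.zeros(n_non, dtype=bool)]
    )
    scales_full = np.concatenate([svg_scales, np.zeros(n_non)])
    values = np.concatenate([svg_values, non_values], axis=1)

    shuffle = rng.permutation(config.n_genes)
    values = values[:, shuffle]
    flags = flags[shuffle]
    scales_full = scales_full[shuffle]

    svg_pool = [g for g, f in zip(gene_ids, flags) if f]
    non_pool = [g for g, f in zip(gene_ids, flags) if not f]
    svg_pick = rng.choice(len(svg_pool), size=need_svg, replace=False)
    non_pick = rng.choice(len(non_pool), size=need_non, replace=False)

    sets = GeneSetCollection()
    per_non = config.genes_per_pathway - config.svg_per_pathway
    for i in range(config.n_pathways):
        chosen_svg = [
            svg_pool[j]
            for j in svg_pick[i * config.svg_per_pathway : (i + 1) * config.svg_per_pathway]
        ]
        chosen_non = [
            non_pool[j] for j in non_pick[i * per_non : (i + 1) * per_non]
        ]
        genes = chosen_svg + chosen_non
        order = rng.permutation(len(genes))
        sets.add(
            f"pathway_{i + 1:02d}",
            f"simulated pathway with {config.svg_per_pathway} SVG genes",
            [genes[j] for j in order],
        )

    expr = ExpressionMatrix(values, coords.spot_ids, gene_ids, layer=NORMALIZED_LOG)
    return SimulatedDataset(
        expr=expr,
        coords=coords,
        cancer_mask=mask,
        svg_flags={g: bool(f) for g, f in zip(gene_ids, flags)},
        scales={g: float(s) for g, s in zip(gene_ids, scales_full)},
        sets=sets,
        config=config,
    )


def build_null_dataset(
    n_spots: int,
    n_genes: int,
    n_pathways: int,
    seed: int,
    genes_per_pathway: Optional[int] = None,
) -> SimulatedDataset:
    """Pure-null dataset: every gene i.i.d. Normal(1, 1), no spatial signal.

    Pathways are random gene subsets (without replacement); all SVG flags
    are False. Intended for type-I-error calibration of the screen.
    """
    rng = np.random.default_rng(seed)
    coords = _grid_coords(n_spots)
    values = rng.normal(1.0, 1.0, size=(n_spots, n_genes))
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    if genes_per_pathway is None:
        genes_per_pathway = max(1, n_genes // max(n_pathways, 1))
    if n_pathways * genes_per_pathway > n_genes:
        raise DataError("not enough genes for the requested pathways")
    pick = rng.choice(n_genes, size=n_pathways * genes_per_pathway, replace=False)
    sets = GeneSetCollection()
    for i in range(n_pathways):
        genes = [gene_ids[j] for j in pick[i * genes_per_pathway : (i + 1) * genes_per_pathway]]
        sets.add(f"null_pathway_{i + 1:02d}", "null pathway", genes)
    expr = ExpressionMatrix(values, coords.spot_ids, gene_ids, layer=NORMALIZED_LOG)
    config = SimulationConfig(
        n_spots=n_spots,
        n_genes=n_genes,
        n_pathways=n_pathways,
        genes_per_pathway=genes_per_pathway,
        svg_per_pathway=0,
        seed=seed,
    )
    return SimulatedDataset(
        expr=expr,
        coords=coords,
        cancer_mask=np.zeros(n_spots, dtype=bool),
        svg_flags={g: False for g in gene_ids},
        scales={g: 0.0 for g in gene_ids},
        sets=sets,
        config=config,
    )
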