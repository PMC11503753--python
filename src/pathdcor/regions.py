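"""Supervised inner/edge contrast of a pathway's gene-gene distance structure.

Spots of one cell type are split into *inner* spots (every spatial
neighbor shares the cell type) and *edge* spots (at least one neighbor
differs). For a pathway with r_i measured genes, the genes become the
samples: each gene's expression vector over the edge spots (length
n_edge) and over the inner spots (length n_in) gives two r_i x r_i gene
Euclidean distance matrices, and the distance correlation between them
measures how similar the pathway's internal structure is across the two
regions. Pathways are ranked by ASCENDING dCor — values near zero flag
divergent behavior between regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dcov
from .containers import (
    CellAnnotation,
    ContrastResult,
    CoordinateMatrix,
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    RegionPartition,
    align_spots,
)
from .preprocess import filter_sets_by_size

NEIGHBOR_RULES = ("knn", "radius", "grid4", "hex6")


@dataclass
class NeighborGraph:
    """Per-spot neighbor lists over the full coordinate set.

    ``grid4`` and ``hex6`` are k-nearest-neighbor graphs with k = 4 / 6,
    intended for square lattices and Visium-style hexagonal lattices.
    k-NN ties at equal distance are broken toward the smaller spot index.
    """

    neighbors: list[np.ndarray]
    spot_ids: list[str]
    rule: str


def build_neighbor_graph(
    coords: CoordinateMatrix,
    rule: str,
    k: Optional[int] = None,
    radius: Optional[float] = None,
) -> NeighborGraph:
    if rule not in NEIGHBOR_RULES:
        raise DataError(f"unknown neighbor rule {rule!r}; one of {NEIGHBOR_RULES}")
    n = coords.n_spots
    if n < 2:
        raise DataError("neighbor graph needs at least 2 spots")
    d = dcov.pairwise_distances(coords.coords)

    if rule == "radius":
        if radius is None or radius <= 0:
            raise DataError("radius rule needs radius > 0")
        neighbors = []
        for i in range(n):
            within = np.nonzero(d[i] <= radius)[0]
            neighbors.append(within[within != i])
        return NeighborGraph(neighbors, list(coords.spot_ids), rule)

    if rule == "knn":
        if k is None or k < 1:
            raise DataError("knn rule needs k >= 1")
    else:
        k = 4 if rule == "grid4" else 6
    if k >= n:
        raise DataError(f"k={k} must be smaller than the spot count {n}")

    idx = np.arange(n)
    neighbors = []
    for i in range(n):
        # stable order on (distance, index); drop self, take k nearest
        order = np.lexsort((idx, d[i]))
        order = order[order != i]
        neighbors.append(np.sort(order[:k]))
    return NeighborGraph(neighbors, list(coords.spot_ids), rule)


def classify_inner_edge(
    annotations: CellAnnotation,
    graph: NeighborGraph,
    cell_type: str,
    isolated_is_inner: bool = True,
) -> RegionPartition:
    """Split spots of ``cell_type`` into inner and edge.

    Inner: every neighbor (of any type) shares the cell type. A spot with
    an empty neighbor list is inner by vacuous truth unless
    ``isolated_is_inner`` is False.
    """
    if annotations.spot_ids != graph.spot_ids:
        ann = {s: l for s, l in zip(annotations.spot_ids, annotations.labels)}
        missing = [s for s in graph.spot_ids if s not in ann]
        if missing:
            raise DataError(f"spots without annotation: {missing[:5]}")
        labels = [ann[s] for s in graph.spot_ids]
    else:
        labels = annotations.labels
    if cell_type not in labels:
        raise DataError(f"cell type {cell_type!r} not present in annotations")

    inner, edge = [], []
    for i, spot in enumerate(graph.spot_ids):
        if labels[i] != cell_type:
            continue
        nb = graph.neighbors[i]
        if len(nb) == 0:
            (inner if isolated_is_inner else edge).append(spot)
        elif all(labels[j] == cell_type for j in nb):
            inner.append(spot)
        else:
            edge.append(spot)
    return RegionPartition(cell_type, inner, edge)


def region_submatrices(
    expr: ExpressionMatrix,
    partition: RegionPartition,
    set_genes: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(G_edge, G_in) value matrices with identical gene columns/order."""
    if partition.n_inner < 2 or partition.n_edge < 2:
        raise DataError(
            f"need >= 2 spots per region, got inner={partition.n_inner}, "
            f"edge={partition.n_edge}"
        )
    measured = set(expr.gene_ids)
    genes = [g for g in set_genes if g in measured]
    if len(genes) < 2:
        raise DataError(f"need >= 2 measured genes, got {len(genes)}")
    sub = expr.subset_genes(genes)
    g_edge = sub.subset_spots(partition.edge_ids).values
    g_in = sub.subset_spots(partition.inner_ids).values
    return g_edge, g_in, genes


def gene_space_dcor(
    g_edge: np.ndarray,
    g_in: np.ndarray,
    standardize: bool = False,
    set_id: str = "",
    description: str = "",
    n_permutations: int = 0,
    seed: Optional[int] = None,
) -> ContrastResult:
    """Distance correlation between the two regions' gene-gene structure.

    Samples are genes: row k of the transposed matrices is gene k's
    expression vector over that region's spots, so the r_i x r_i distance
    matrices are gene Euclidean distances. ``standardize`` centers/scales
    each gene within its region first (off by default; the statistic is
    already invariant to a global rescaling of either region). An optional
    gene-label permutation p-value is available via ``n_permutations``.
    """
    x = np.asarray(g_edge, dtype=float).T  # genes x n_edge
    y = np.asarray(g_in, dtype=float).T    # genes x n_in
    if x.shape[0] != y.shape[0]:
        raise DataError(
            f"gene counts differ between regions: {x.shape[0]} vs {y.shape[0]}"
        )
    if x.shape[0] < 2:
        raise DataError("need at least 2 genes")
    if standardize:
        x = _standardize_rows(x)
        y = _standardize_rows(y)
    if n_permutations > 0:
        res = dcov.permutation_test(
            x, y, n_permutations=n_permutations, seed=seed, permute_side="X"
        )
    else:
        res = dcov.dcor(x, y)
    return ContrastResult(
        set_id=set_id,
        description=description,
        n_genes_used=x.shape[0],
        dcor=res.dcor,
        dcov2=res.dcov2,
        p_value=res.p_value,
    )


def _standardize_rows(m: np.ndarray) -> np.ndarray:
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    return (m - mu) / np.where(sd > 0, sd, 1.0)


def rank_divergent(results: Sequence[ContrastResult]) -> pd.DataFrame:
    """Results table sorted by ascending dCor (ties by set_id)."""
    table = pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "description": r.description,
                "n_genes_used": r.n_genes_used,
                "dcov2": r.dcov2,
                "dcor": r.dcor,
                "p_value": r.p_value,
            }
            for r in results
        ],
        columns=["set_id", "description", "n_genes_used", "dcov2", "dcor", "p_value"],
    )
    if len(table):
        table = table.sort_values(
            ["dcor", "set_id"], ascending=[True, True], kind="mergesort"
        ).reset_index(drop=True)
    return table


def run_region_contrast(
    expr: ExpressionMatrix,
    coords: CoordinateMatrix,
    annotations: CellAnnotation,
    sets: GeneSetCollection,
    cell_type: str,
    neighbor_rule: str = "hex6",
    k: Optional[int] = None,
    radius: Optional[float] = None,
    set_size_min: int = 12,
    set_size_max: int = 100,
    standardize: bool = False,
    n_permutations: int = 0,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, RegionPartition, list[dict]]:
    """End-to-end contrast: classify spots, test every set, rank ascending."""
    coords, annotations = align_spots(expr, coords, annotations)
    graph = build_neighbor_graph(coords, neighbor_rule, k=k, radius=radius)
    partition = classify_inner_edge(annotations, graph, cell_type)
    if partition.n_inner < 2 or partition.n_edge < 2:
        raise DataError(
            f"cell type {cell_type!r} yields inner={partition.n_inner}, "
            f"edge={partition.n_edge}; need >= 2 in each region"
        )
    sets = filter_sets_by_size(sets, set_size_min, set_size_max)
    results: list[ContrastResult] = []
    skipped: list[dict] = []
    for s in sets:
        try:
            g_edge, g_in, genes = region_submatrices(expr, partition, s.genes)
        except DataError as exc:
            skipped.append({"set_id": s.set_id, "reason": str(exc)})
            continue
        results.append(
            gene_space_dcor(
                g_edge,
                g_in,
                standardize=standardize,
                set_id=s.set_id,
                description=s.description,
                n_permutations=n_permutations,
                seed=seed,
            )
        )
    return rank_divergent(results), partition, skipped
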