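"""Gene filtering, library-size normalization, and pathway submatrix extraction.

Raw counts are filtered by detection (a gene must be nonzero in at least
``min_cells`` spots), scaled so every spot's total equals a common target
(the median spot total by default), and natural-log transformed via
x -> ln(1 + x). Gene sets are filtered on their annotated size before
intersection with the measured genes; a small post-intersection guard
(``min_genes_used``) skips sets that barely overlap the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .containers import (
    DataError,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    NORMALIZED_LOG,
    RAW_COUNTS,
)


@dataclass
class PreprocessConfig:
    """Defaults follow the standard pathway-screen workflow on Visium-style
    data: detection in >= 20 spots, median-total normalization with ln(1+x),
    and pathway sizes 12-100 (annotated) with at least 5 measured genes."""

    min_cells: int = 20
    target_sum: Union[float, str] = "median"
    set_size_min: int = 12
    set_size_max: int = 100
    min_genes_used: int = 5

    def __post_init__(self) -> None:
        if self.min_cells < 0:
            raise DataError("min_cells must be >= 0")
        if self.set_size_min > self.set_size_max:
            raise DataError("set_size_min must be <= set_size_max")
        if self.min_genes_used < 1:
            raise DataError("min_genes_used must be >= 1")
        if isinstance(self.target_sum, str):
            if self.target_sum != "median":
                raise DataError("target_sum must be a positive float or 'median'")
        elif self.target_sum <= 0:
            raise DataError("target_sum must be positive")


def filter_genes_by_min_cells(
    expr: ExpressionMatrix, min_cells: int
) -> ExpressionMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells`` spots."""
    if expr.layer != RAW_COUNTS:
        raise DataError("gene detection filtering applies to raw counts")
    detected = (expr.values > 0).sum(axis=0)
    keep = detected >= min_cells
    if not keep.any():
        raise DataError(
            f"all genes removed by min_cells={min_cells} detection filter"
        )
    return ExpressionMatrix(
        expr.values[:, keep],
        list(expr.spot_ids),
        [g for g, k in zip(expr.gene_ids, keep) if k],
        layer=RAW_COUNTS,
    )


def normalize_and_log(
    expr: ExpressionMatrix, target_sum: Union[float, str] = "median"
) -> ExpressionMatrix:
    """Scale each spot to a common total, then apply x -> ln(1 + x)."""
    if expr.layer != RAW_COUNTS:
        raise DataError("normalization applies to raw counts")
    totals = expr.values.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise DataError(
            f"spot with zero total count: {expr.spot_ids[zero[0]]!r}"
        )
    target = float(np.median(totals)) if target_sum == "median" else float(target_sum)
    scaled = expr.values * (target / totals)[:, None]
    return ExpressionMatrix(
        np.log1p(scaled),
        list(expr.spot_ids),
        list(expr.gene_ids),
        layer=NORMALIZED_LOG,
    )


def filter_sets_by_size(
    sets: GeneSetCollection, set_size_min: int, set_size_max: int
) -> GeneSetCollection:
    """Keep sets whose annotated size lies in [set_size_min, set_size_max]."""
    return GeneSetCollection(
        [s for s in sets if set_size_min <= s.size <= set_size_max]
    )


@dataclass
class PathwaySubmatrix:
    """Expression columns of one gene set; ``expr`` is None when skipped."""

    set_id: str
    expr: ExpressionMatrix | None
    n_genes_annotated: int
    n_genes_used: int

    @property
    def skipped(self) -> bool:
        return self.expr is None


def extract_pathway_submatrix(
    expr: ExpressionMatrix,
    set_id: str,
    sets: GeneSetCollection,
    min_genes_used: int = 5,
) -> PathwaySubmatrix:
    """Columns of ``expr`` for the genes of one set, in set order.

    Returns a skip signal (``expr=None``) rather than an error when fewer
    than ``min_genes_used`` set genes are measured.
    """
    gene_set: GeneSet = sets[set_id]
    measured = set(expr.gene_ids)
    present = [g for g in gene_set.genes if g in measured]
    if len(present) < min_genes_used:
        return PathwaySubmatrix(set_id, None, gene_set.size, len(present))
    return PathwaySubmatrix(
        set_id, expr.subset_genes(present), gene_set.size, len(present)
    )
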