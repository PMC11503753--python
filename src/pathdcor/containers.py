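"""In-memory domain containers shared by every analysis module.

All readers produce these objects and all statistics consume them; nothing
downstream ever touches a file path. Expression values are stored dense
(spots x genes) because the distance-matrix engine is O(n^2) anyway and the
spot counts this tool targets (hundreds to a few thousand) fit comfortably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np


class PathdcorError(Exception):
    """Base class for all errors raised by this package."""


class DataError(PathdcorError):
    """Malformed or inconsistent input data."""


class AlignmentError(DataError):
    """Spot identifiers of two inputs do not describe the same spot set."""


#: layer tags for :class:`ExpressionMatrix`
RAW_COUNTS = "raw_counts"
NORMALIZED_LOG = "normalized_log"
_LAYERS = (RAW_COUNTS, NORMALIZED_LOG)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Spots x genes numeric matrix with identifiers on both axes.

    Parameters
    ----------
    values
        Dense ``(n_spots, n_genes)`` float array. Must be finite; the
        ``raw_counts`` layer must additionally be nonnegative.
    spot_ids, gene_ids
        Unique string identifiers aligned to rows / columns.
    layer
        Either ``"raw_counts"`` or ``"normalized_log"``.
    """

    values: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    layer: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, r = self.values.shape
        if n != len(self.spot_ids):
            raise DataError(
                f"matrix has {n} rows but {len(self.spot_ids)} spot ids"
            )
        if r != len(self.gene_ids):
            raise DataError(
                f"matrix has {r} columns but {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.spot_ids, "spot")
        _check_unique(self.gene_ids, "gene")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite values")
        if self.layer not in _LAYERS:
            raise DataError(f"unknown layer tag {self.layer!r}")
        if self.layer == RAW_COUNTS and np.any(self.values < 0):
            raise DataError("raw_counts layer contains negative values")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Column subset in the order of ``genes`` (all must be measured)."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        try:
            cols = [index[g] for g in genes]
        except KeyError as exc:
            raise DataError(f"gene not in matrix: {exc.args[0]!r}") from None
        return ExpressionMatrix(
            self.values[:, cols], list(self.spot_ids), [str(g) for g in genes],
            layer=self.layer,
        )

    def subset_spots(self, spot_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.spot_ids)}
        try:
            rows = [index[s] for s in spot_ids]
        except KeyError as exc:
            raise DataError(f"spot not in matrix: {exc.args[0]!r}") from None
        return ExpressionMatrix(
            self.values[rows], [str(s) for s in spot_ids],
            list(self.gene_ids), layer=self.layer,
        )


@dataclass
class CoordinateMatrix:
    """Spots x d spatial positions (d >= 1, typically 2)."""

    coords: np.ndarray
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 1:
            self.coords = self.coords[:, None]
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise DataError("coordinates must form an n x d matrix, d >= 1")
        self.spot_ids = [str(s) for s in self.spot_ids]
        if self.coords.shape[0] != len(self.spot_ids):
            raise DataError("coordinate rows do not match spot id count")
        _check_unique(self.spot_ids, "spot")
        if not np.all(np.isfinite(self.coords)):
            raise DataError("coordinates contain non-finite values")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    def reorder(self, spot_ids: Sequence[str]) -> "CoordinateMatrix":
        index = {s: i for i, s in enumerate(self.spot_ids)}
        try:
            rows = [index[s] for s in spot_ids]
        except KeyError as exc:
            raise AlignmentError(
                f"spot missing from coordinates: {exc.args[0]!r}"
            ) from None
        return CoordinateMatrix(self.coords[rows], [str(s) for s in spot_ids])


@dataclass
class CellAnnotation:
    """Per-spot cell-type labels."""

    spot_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.labels = [str(l).strip() for l in self.labels]
        if len(self.spot_ids) != len(self.labels):
            raise DataError("annotation ids and labels differ in length")
        _check_unique(self.spot_ids, "spot")
        if any(l == "" for l in self.labels):
            raise DataError("empty cell-type label")

    def reorder(self, spot_ids: Sequence[str]) -> "CellAnnotation":
        index = {s: i for i, s in enumerate(self.spot_ids)}
        try:
            rows = [index[s] for s in spot_ids]
        except KeyError as exc:
            raise AlignmentError(
                f"spot missing from annotations: {exc.args[0]!r}"
            ) from None
        return CellAnnotation(
            [str(s) for s in spot_ids], [self.labels[i] for i in rows]
        )


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """Ordered collection of named gene sets (pathways).

    Within each set genes are deduplicated preserving first occurrence;
    set ids must be unique.
    """

    def __init__(self, sets: Optional[Sequence[GeneSet]] = None) -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets or ():
            self.add(s.set_id, s.description, s.genes)

    def add(self, set_id: str, description: str, genes: Sequence[str]) -> None:
        if set_id in self._sets:
            raise DataError(f"duplicate gene set id: {set_id!r}")
        deduped: list[str] = []
        seen: set[str] = set()
        for g in genes:
            g = str(g)
            if g not in seen:
                seen.add(g)
                deduped.append(g)
        self._sets[set_id] = GeneSet(set_id, description, tuple(deduped))

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._sets

    def __getitem__(self, set_id: str) -> GeneSet:
        try:
            return self._sets[set_id]
        except KeyError:
            raise DataError(f"unknown gene set id: {set_id!r}") from None

    @property
    def set_ids(self) -> list[str]:
        return list(self._sets)


@dataclass
class DcorResult:
    """Distance covariance / correlation with an optional permutation p-value.

    ``dcor`` is the square root R_n of the normalized statistic, in [0, 1];
    ``dcov2`` is the squared empirical distance covariance V_n^2. When
    ``n_permutations`` is 0, ``p_value`` is ``None``.
    """

    dcov2: float
    dcor: float
    n: int
    n_permutations: int = 0
    p_value: Optional[float] = None
    seed: Optional[int] = None


@dataclass
class RegionPartition:
    """Inner/edge split of the spots of one cell type."""

    cell_type: str
    inner_ids: list[str]
    edge_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.inner_ids) & set(self.edge_ids)
        if overlap:
            raise DataError(f"spots in both inner and edge: {sorted(overlap)[:3]}")

    @property
    def n_inner(self) -> int:
        return len(self.inner_ids)

    @property
    def n_edge(self) -> int:
        return len(self.edge_ids)


@dataclass
class ContrastResult:
    """Gene-space distance correlation between two regions for one set."""

    set_id: str
    description: str
    n_genes_used: int
    dcor: float
    dcov2: float
    p_value: Optional[float] = None


def align_spots(
    expr: ExpressionMatrix,
    coords: CoordinateMatrix,
    annotations: Optional[CellAnnotation] = None,
):
    """Align coordinates (and annotations) to the expression spot order.

    The three inputs must describe exactly the same spot set; any mismatch
    is an error rather than a silent subset, because dropping spots changes
    n and with it every statistic downstream.
    """
    e, c = set(expr.spot_ids), set(coords.spot_ids)
    if e != c:
        missing = sorted(e ^ c)[:5]
        raise AlignmentError(
            f"expression and coordinates disagree on the spot set "
            f"(first differences: {missing})"
        )
    coords = coords.reorder(expr.spot_ids)
    if annotations is None:
        return coords, None
    a = set(annotations.spot_ids)
    if a != e:
        missing = sorted(e ^ a)[:5]
        raise AlignmentError(
            f"expression and annotations disagree on the spot set "
            f"(first differences: {missing})"
        )
    return coords, annotations.reorder(expr.spot_ids)
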