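"""Readers and writers for the on-disk formats the tool touches.

Expression comes in either as a Matrix Market triplet file plus one-id-per-
line spot/gene label files, or as a dense delimited table (spots in rows,
gene ids in the header). Gene sets use the standard GMT layout. Results go
out as TSV with enough digits to round-trip.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    CellAnnotation,
    CoordinateMatrix,
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    RAW_COUNTS,
)

_DIALECTS = ("matrix-market-triplet", "delimited-dense")


def _read_id_file(path) -> list[str]:
    """One id per line; extra tab-separated columns ignored (first used)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            ids.append(line.split("\t")[0].strip())
    return ids


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise DataError(
        f"cannot sniff delimiter of {path}: expected tab or comma"
    )


def read_expression_matrix(
    path_matrix,
    path_spots=None,
    path_genes=None,
    dialect: Optional[str] = None,
    layer: str = RAW_COUNTS,
) -> ExpressionMatrix:
    """Read an expression matrix (``raw_counts`` layer unless stated).

    ``matrix-market-triplet`` requires the two label files; the matrix may
    be stored spots x genes or genes x spots — orientation is resolved by
    matching label-file lengths, and a square matrix with equally long
    label files is an explicit error. ``delimited-dense`` expects gene ids
    in the header row and spot ids in the first column. Pass
    ``layer="normalized_log"`` for data already on the normalized scale
    (e.g. simulator output), which may be negative.
    """
    if dialect is None:
        dialect = (
            "matrix-market-triplet"
            if str(path_matrix).endswith(".mtx")
            else "delimited-dense"
        )
    if dialect not in _DIALECTS:
        raise DataError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")

    if dialect == "matrix-market-triplet":
        if path_spots is None or path_genes is None:
            raise DataError("matrix-market input needs spot and gene label files")
        mat = scipy.io.mmread(path_matrix)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        spots = _read_id_file(path_spots)
        genes = _read_id_file(path_genes)
        n, r = mat.shape
        if n == 0 or len(spots) == 0:
            raise DataError("no spots in expression input")
        if (n, r) == (len(spots), len(genes)) and n == r and len(spots) == len(genes):
            raise DataError(
                "square matrix with equally long label files: orientation ambiguous"
            )
        if (n, r) == (len(spots), len(genes)):
            pass
        elif (r, n) == (len(spots), len(genes)):
            mat = mat.T
        else:
            raise DataError(
                f"matrix shape {mat.shape} matches neither "
                f"({len(spots)} spots, {len(genes)} genes) nor its transpose"
            )
        return ExpressionMatrix(mat, spots, genes, layer=layer)

    try:
        sep = _sniff_sep(path_matrix)
        df = pd.read_csv(path_matrix, sep=sep, index_col=0)
    except (pd.errors.EmptyDataError, DataError):
        raise DataError("no spots in expression input") from None
    if df.shape[0] == 0:
        raise DataError("no spots in expression input")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric expression entry: {exc}") from None
    return ExpressionMatrix(
        values,
        [str(s) for s in df.index],
        [str(g) for g in df.columns],
        layer=layer,
    )


def read_coordinates(path) -> CoordinateMatrix:
    """Read a spot-id + coordinate-columns table (TSV or CSV)."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 1:
        raise DataError("coordinate file needs at least one coordinate column")
    if df.isna().any().any():
        raise DataError("missing coordinate value")
    try:
        coords = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric coordinate: {exc}") from None
    return CoordinateMatrix(coords, [str(s) for s in df.index])


def read_cell_annotations(path) -> CellAnnotation:
    """Read a two-column (spot id, cell-type label) table."""
    try:
        sep = _sniff_sep(path)
        df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    except (pd.errors.EmptyDataError, DataError):
        raise DataError("no annotations in file") from None
    if df.shape[0] == 0:
        raise DataError("no annotations in file")
    if df.shape[1] < 2:
        raise DataError("annotation file needs (spot id, label) columns")
    return CellAnnotation(
        [str(s) for s in df.iloc[:, 0]],
        [str(l) for l in df.iloc[:, 1]],
    )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB gene1 TAB gene2 ...``."""
    sets = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            set_id, description, *genes = fields
            sets.add(set_id, description, [g for g in genes if g.strip()])
    return sets


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *s.genes]) + "\n")


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write a results table as TSV; floats keep >= 6 significant digits."""
    results.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_coordinates(coords: CoordinateMatrix, path) -> None:
    d = coords.coords.shape[1]
    cols = ["x", "y", "z"][:d] if d <= 3 else [f"c{i}" for i in range(d)]
    df = pd.DataFrame(coords.coords, index=coords.spot_ids, columns=cols)
    df.index.name = "spot"
    df.to_csv(path, sep="\t", float_format="%.8g")


def write_expression_dense(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.spot_ids, columns=expr.gene_ids)
    df.index.name = "spot"
    df.to_csv(path, sep="\t", float_format="%.8g")
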