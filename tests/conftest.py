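import numpy as np
import pytest

from pathdcor import (
    CellAnnotation,
    CoordinateMatrix,
    ExpressionMatrix,
    GeneSetCollection,
)


@pytest.fixture
def tiny_expr():
    """3 spots x 4 genes raw counts."""
    values = np.array(
        [
            [0, 1, 2, 3],
            [4, 0, 6, 1],
            [0, 0, 1, 2],
        ],
        dtype=float,
    )
    return ExpressionMatrix(values, ["s1", "s2", "s3"], ["gA", "gB", "gC", "gD"])


@pytest.fixture
def tiny_coords():
    return CoordinateMatrix(
        np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]), ["s1", "s2", "s3"]
    )


@pytest.fixture
def tiny_sets():
    sets = GeneSetCollection()
    sets.add("S1", "first", ["gA", "gB", "gC"])
    sets.add("S2", "second", ["gC", "gD", "gZ"])
    return sets


@pytest.fixture
def grid_block_annotation():
    """10x10 unit grid with a 4x4 block of type T (rows/cols 3..6) in type S."""
    coords, labels, ids = [], [], []
    for i in range(10):
        for j in range(10):
            ids.append(f"s{i}_{j}")
            coords.append((float(i), float(j)))
            labels.append("T" if 3 <= i <= 6 and 3 <= j <= 6 else "S")
    return (
        CoordinateMatrix(np.array(coords), ids),
        CellAnnotation(ids, labels),
    )
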