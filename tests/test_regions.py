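"""Neighbor graphs, inner/edge classification, and the gene-space contrast."""

import numpy as np
import pytest

import oracles
from pathdcor import (
    CellAnnotation,
    ContrastResult,
    CoordinateMatrix,
    DataError,
    ExpressionMatrix,
    RegionPartition,
    build_neighbor_graph,
    classify_inner_edge,
    gene_space_dcor,
    rank_divergent,
    region_submatrices,
)
from pathdcor.regions import run_region_contrast
from pathdcor import GeneSetCollection


def _coords(points, prefix="s"):
    pts = np.asarray(points, dtype=float)
    return CoordinateMatrix(pts, [f"{prefix}{i}" for i in range(len(pts))])


class TestNeighborGraph:
    def test_knn_tie_broken_toward_smaller_index(self):
        coords = _coords([(0, 0), (1, 0), (2, 0)])
        graph = build_neighbor_graph(coords, "knn", k=1)
        assert list(graph.neighbors[1]) == [0]

    def test_radius_below_min_spacing_gives_empty_lists(self):
        coords = _coords([(0, 0), (1, 0), (2, 0)])
        graph = build_neighbor_graph(coords, "radius", radius=0.5)
        assert all(len(nb) == 0 for nb in graph.neighbors)

    def test_grid4_interior_neighbors_are_axis_adjacent(self):
        pts = [(i, j) for i in range(5) for j in range(5)]
        coords = _coords(pts)
        graph = build_neighbor_graph(coords, "grid4")
        for idx, (i, j) in enumerate(pts):
            if 0 < i < 4 and 0 < j < 4:
                expected = sorted(
                    pts.index(p)
                    for p in [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
                )
                assert list(graph.neighbors[idx]) == expected

    def test_k_too_large_rejected(self):
        with pytest.raises(DataError):
            build_neighbor_graph(_coords([(0, 0), (1, 1)]), "knn", k=2)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(DataError):
            build_neighbor_graph(_coords([(0, 0), (1, 1)]), "radius", radius=0.0)


class TestClassifyInnerEdge:
    def test_uniform_type_grid_is_all_inner(self):
        pts = [(i, j) for i in range(3) for j in range(3)]
        coords = _coords(pts)
        ann = CellAnnotation(coords.spot_ids, ["T"] * 9)
        graph = build_neighbor_graph(coords, "grid4")
        part = classify_inner_edge(ann, graph, "T")
        assert part.n_inner == 9 and part.n_edge == 0

    def test_chain_with_type_change(self):
        coords = _coords([(0, 0), (1, 0), (2, 0)])
        ann = CellAnnotation(coords.spot_ids, ["A", "A", "B"])
        graph = build_neighbor_graph(coords, "radius", radius=1.0)
        part_a = classify_inner_edge(ann, graph, "A")
        assert part_a.inner_ids == ["s0"] and part_a.edge_ids == ["s1"]
        part_b = classify_inner_edge(ann, graph, "B")
        assert part_b.edge_ids == ["s2"] and part_b.inner_ids == []

    def test_block_in_grid_core_and_boundary(self, grid_block_annotation):
        coords, ann = grid_block_annotation
        graph = build_neighbor_graph(coords, "grid4")
        part = classify_inner_edge(ann, graph, "T")
        assert part.n_inner == 4 and part.n_edge == 12
        core = {f"s{i}_{j}" for i in (4, 5) for j in (4, 5)}
        assert set(part.inner_ids) == core

    def test_isolated_spot_inner_by_default_configurable(self):
        coords = _coords([(0, 0), (100, 100), (101, 100)])
        ann = CellAnnotation(coords.spot_ids, ["T", "T", "S"])
        graph = build_neighbor_graph(coords, "radius", radius=2.0)
        assert classify_inner_edge(ann, graph, "T").inner_ids == ["s0"]
        part = classify_inner_edge(ann, graph, "T", isolated_is_inner=False)
        assert "s0" in part.edge_ids

    def test_unknown_cell_type_rejected(self):
        coords = _coords([(0, 0), (1, 0)])
        ann = CellAnnotation(coords.spot_ids, ["A", "A"])
        graph = build_neighbor_graph(coords, "knn", k=1)
        with pytest.raises(DataError):
            classify_inner_edge(ann, graph, "missing")

    def test_agrees_with_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(42)
        for rep in range(10):
            n = int(rng.integers(20, 80))
            pts = rng.uniform(0, 10, size=(n, 2))
            labels = list(rng.choice(["A", "B", "C"], size=n))
            coords = _coords(pts)
            ann = CellAnnotation(coords.spot_ids, labels)
            graph = build_neighbor_graph(coords, "knn", k=5)
            part = classify_inner_edge(ann, graph, "A")
            inner_bf, edge_bf = oracles.brute_force_inner_edge(pts, labels, "A", 5)
            assert part.inner_ids == [f"s{i}" for i in inner_bf]
            assert part.edge_ids == [f"s{i}" for i in edge_bf]


class TestRegionSubmatrices:
    def _expr(self):
        rng = np.random.default_rng(0)
        return ExpressionMatrix(
            rng.normal(size=(6, 3)),
            [f"s{i}" for i in range(6)],
            ["gA", "gB", "gC"],
            layer="normalized_log",
        )

    def test_single_edge_spot_rejected(self):
        part = RegionPartition("T", ["s0", "s1"], ["s2"])
        with pytest.raises(DataError, match=">= 2 spots"):
            region_submatrices(self._expr(), part, ["gA", "gB"])

    def test_gene_order_fixed_by_set_not_matrix(self):
        expr = self._expr()
        reordered = expr.subset_genes(["gC", "gA", "gB"])
        part = RegionPartition("T", ["s0", "s1"], ["s2", "s3"])
        a_edge, a_in, _ = region_submatrices(expr, part, ["gB", "gC"])
        b_edge, b_in, _ = region_submatrices(reordered, part, ["gB", "gC"])
        np.testing.assert_array_equal(a_edge, b_edge)
        np.testing.assert_array_equal(a_in, b_in)

    def test_values_match_direct_indexing(self):
        expr = self._expr()
        part = RegionPartition("T", ["s1", "s3"], ["s0", "s5"])
        g_edge, g_in, genes = region_submatrices(expr, part, ["gA", "gC"])
        np.testing.assert_array_equal(g_edge, expr.values[np.ix_([0, 5], [0, 2])])
        np.testing.assert_array_equal(g_in, expr.values[np.ix_([1, 3], [0, 2])])
        assert genes == ["gA", "gC"]


class TestGeneSpaceDcor:
    def test_identical_regions_give_dcor_one(self):
        g = np.random.default_rng(0).normal(size=(20, 8))
        assert gene_space_dcor(g, g).dcor == pytest.approx(1.0, abs=1e-9)

    def test_two_gene_degeneracy_is_exactly_one(self):
        rng = np.random.default_rng(1)
        res = gene_space_dcor(rng.normal(size=(5, 2)), rng.normal(size=(7, 2)))
        assert res.dcor == pytest.approx(1.0, abs=1e-12)
        assert res.n_genes_used == 2

    def test_invariant_to_simultaneous_gene_reordering(self):
        rng = np.random.default_rng(2)
        g_edge, g_in = rng.normal(size=(10, 6)), rng.normal(size=(12, 6))
        perm = rng.permutation(6)
        base = gene_space_dcor(g_edge, g_in).dcor
        permuted = gene_space_dcor(g_edge[:, perm], g_in[:, perm]).dcor
        assert permuted == pytest.approx(base, abs=1e-12)

    def test_invariant_to_positive_region_rescaling(self):
        rng = np.random.default_rng(3)
        g_edge, g_in = rng.normal(size=(10, 6)), rng.normal(size=(12, 6))
        base = gene_space_dcor(g_edge, g_in).dcor
        scaled = gene_space_dcor(g_edge * 3.7, g_in).dcor
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_engine_route_matches_standalone_naive(self):
        rng = np.random.default_rng(4)
        g_edge, g_in = rng.normal(size=(8, 7)), rng.normal(size=(9, 7))
        ours = gene_space_dcor(g_edge, g_in).dcor
        naive = oracles.naive_dcor(g_edge.T, g_in.T)
        assert ours == pytest.approx(naive, abs=1e-10)

    def test_gene_count_mismatch_rejected(self):
        with pytest.raises(DataError):
            gene_space_dcor(np.zeros((4, 3)), np.zeros((4, 5)))


class TestRankDivergent:
    def test_sorted_ascending(self):
        results = [
            ContrastResult("b", "", 5, 0.119, 0.1),
            ContrastResult("a", "", 5, 0.0, 0.0),
            ContrastResult("c", "", 5, 0.083, 0.05),
        ]
        table = rank_divergent(results)
        assert list(table.set_id) == ["a", "c", "b"]
        assert list(table.dcor) == [0.0, 0.083, 0.119]

    def test_ties_broken_by_set_id(self):
        results = [
            ContrastResult("z", "", 3, 0.5, 0.1),
            ContrastResult("a", "", 3, 0.5, 0.1),
        ]
        assert list(rank_divergent(results).set_id) == ["a", "z"]

    def test_empty_input_empty_table(self):
        assert len(rank_divergent([])) == 0


class TestRunRegionContrast:
    def test_end_to_end_on_block_fixture(self, grid_block_annotation):
        coords, ann = grid_block_annotation
        rng = np.random.default_rng(0)
        expr = ExpressionMatrix(
            rng.normal(size=(100, 20)),
            coords.spot_ids,
            [f"g{j}" for j in range(20)],
            layer="normalized_log",
        )
        sets = GeneSetCollection()
        sets.add("P1", "first", [f"g{j}" for j in range(12)])
        sets.add("P2", "second", [f"g{j}" for j in range(8, 20)])
        table, partition, skipped = run_region_contrast(
            expr, coords, ann, sets, "T",
            neighbor_rule="grid4", set_size_min=1, set_size_max=100,
        )
        assert partition.n_inner == 4 and partition.n_edge == 12
        assert len(table) == 2 and skipped == []
        assert list(table.dcor) == sorted(table.dcor)
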