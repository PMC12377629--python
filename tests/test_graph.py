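"""Contiguity construction, spatial lags and Moran's I."""

import numpy as np
import pytest

from frontiercar.graph import (AreaGraph, IslandWarning, build_adjacency,
                               morans_i, morans_i_permutation,
                               read_adjacency_csv, read_geojson, spatial_lag,
                               write_geojson)

from conftest import grid_graph, grid_polygons


class TestBuildAdjacency:
    @pytest.mark.parametrize(
        "nrows,ncols,rule,n_edges,degree",
        [
            (2, 2, "queen", 6, 3),   # complete graph on 4 mutually touching cells
            (2, 2, "rook", 4, 2),    # diagonal pairs share only a point
        ],
    )
    def test_2x2_grid(self, nrows, ncols, rule, n_edges, degree):
        g = grid_graph(nrows, ncols, rule)
        assert len(g.edges) == n_edges
        assert np.all(g.degrees == degree)

    @pytest.mark.parametrize("rule", ["queen", "rook"])
    def test_3x3_matches_brute_force(self, rule):
        """Edge sets equal brute-force enumeration over all 36 cell pairs."""
        polys = grid_polygons(3, 3)
        g = grid_graph(3, 3, rule)
        expected = set()
        for i in range(9):
            for j in range(i + 1, 9):
                inter = polys[i].intersection(polys[j])
                if inter.is_empty:
                    continue
                if rule == "rook" and inter.length == 0:
                    continue
                expected.add((i, j))
        assert set(g.edges) == expected
        assert len(g.edges) == (20 if rule == "queen" else 12)

    def test_W_matches_edge_set(self, grid3x3_queen):
        W = grid3x3_queen.W
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0)
        assert set(map(tuple, np.argwhere(np.triu(W) > 0))) == set(grid3x3_queen.edges)

    def test_rebuild_from_own_edges_is_idempotent(self, grid3x3_queen):
        g = grid3x3_queen
        g2 = AreaGraph.from_edge_ids(g.unit_ids,
                                     [(g.unit_ids[i], g.unit_ids[j])
                                      for i, j in g.edges])
        assert g2.edges == g.edges

    def test_empty_geometry_names_unit(self):
        from shapely.geometry import Polygon
        with pytest.raises(ValueError, match="bad_unit"):
            build_adjacency([grid_polygons(1, 2)[0], Polygon()],
                            unit_ids=["ok", "bad_unit"])

    def test_island_warns_and_is_retained(self):
        from shapely.geometry import box
        polys = [box(0, 0, 1, 1), box(1, 0, 2, 1), box(10, 10, 11, 11)]
        with pytest.warns(IslandWarning):
            g = build_adjacency(polys, unit_ids=["a", "b", "far"])
        assert g.island_ids == ("far",)
        assert g.K == 3

    def test_geojson_roundtrip(self, tmp_path):
        g = grid_graph(3, 3)
        write_geojson(g, tmp_path / "units.geojson",
                      properties={"val": np.arange(9)})
        g2 = read_geojson(tmp_path / "units.geojson")
        assert len(g2.edges) == len(g.edges)
        assert [str(u) for u in g2.unit_ids] == [str(u) for u in g.unit_ids]

    def test_edge_csv_roundtrip(self, tmp_path, grid3x3_rook):
        path = tmp_path / "edges.csv"
        grid3x3_rook.write_edges_csv(path)
        g2 = read_adjacency_csv(path)
        assert len(g2.edges) == len(grid3x3_rook.edges)


class TestSpatialLag:
    def test_constant_vector_is_fixed_point(self, grid3x3_queen):
        lag = spatial_lag(grid3x3_queen, np.full(9, 4.2))
        assert np.allclose(lag, 4.2)

    def test_path_graph_means(self, path_graph):
        lag = spatial_lag(path_graph, [0.0, 3.0, 6.0])
        assert np.allclose(lag, [3.0, 3.0, 3.0])

    def test_3x3_rook_hand_computed(self, grid3x3_rook):
        """All 9 entries equal the hand-computed neighbor means of row index."""
        x = np.repeat([0.0, 1.0, 2.0], 3)  # row index, row-major layout
        lag = spatial_lag(grid3x3_rook, x)
        #       corners: 2 nbrs; edge-mid: 3 nbrs; center: 4 nbrs
        expected = np.array([
            (1 + 0) / 2, (0 + 0 + 1) / 3, (0 + 1) / 2,
            (0 + 2 + 1) / 3, (1 + 1 + 0 + 2) / 4, (0 + 2 + 1) / 3,
            (1 + 2) / 2, (2 + 2 + 1) / 3, (1 + 2) / 2,
        ])
        assert np.allclose(lag, expected)

    def test_affine_equivariance(self, grid3x3_queen, rng):
        x = rng.normal(size=9)
        lag = spatial_lag(grid3x3_queen, x)
        assert np.allclose(spatial_lag(grid3x3_queen, 2.5 * x - 1.0),
                           2.5 * lag - 1.0)

    def test_island_gets_nan(self):
        g = AreaGraph(unit_ids=("a", "b", "c"), edges=((0, 1),))
        lag = spatial_lag(g, [1.0, 2.0, 3.0])
        assert np.isnan(lag[2]) and lag[0] == 2.0

    def test_all_island_graph_errors(self):
        g = AreaGraph(unit_ids=("a", "b"), edges=())
        with pytest.raises(ValueError, match="island"):
            spatial_lag(g, [1.0, 2.0])


class TestMoransI:
    def test_checkerboard_is_minus_one(self, grid4x4_rook):
        x = np.array([(-1.0) ** (r + c) for r in range(4) for c in range(4)])
        assert morans_i(grid4x4_rook, x) == pytest.approx(-1.0)

    def test_clustered_blocks_positive(self, grid4x4_rook):
        x = np.array([0.0 if c < 2 else 1.0 for _ in range(4) for c in range(4)])
        assert morans_i(grid4x4_rook, x) > 0

    def test_permutation_null_expectation(self, grid4x4_rook, rng):
        """Mean of I over shuffles approximates -1/(K-1)."""
        x = rng.normal(size=16)
        xc = x - x.mean()
        ei, ej = grid4x4_rook.edge_arrays
        scale = 16 / (2.0 * len(ei) * (xc @ xc))
        perms = rng.permuted(np.tile(xc, (10000, 1)), axis=1)
        vals = scale * 2.0 * np.sum(perms[:, ei] * perms[:, ej], axis=1)
        assert vals.mean() == pytest.approx(-1.0 / 15, abs=0.01)

    def test_affine_invariance(self, grid4x4_rook, rng):
        x = rng.normal(size=16)
        assert morans_i(grid4x4_rook, x) == pytest.approx(
            morans_i(grid4x4_rook, -3.0 * x + 7.0))

    def test_zero_variance_errors(self, grid4x4_rook):
        with pytest.raises(ValueError, match="variance"):
            morans_i(grid4x4_rook, np.ones(16))

    def test_strong_cluster_min_p(self):
        g = grid_graph(6, 6, "rook")
        x = np.array([0.0 if c < 3 else 1.0 for _ in range(6) for c in range(6)])
        stat, p = morans_i_permutation(g, x, n_perm=999, seed=1)
        assert stat > 0
        assert p == pytest.approx(1.0 / 1000)

    def test_seed_reproducible_and_in_unit_interval(self, grid4x4_rook, rng):
        x = rng.normal(size=16)
        r1 = morans_i_permutation(grid4x4_rook, x, n_perm=199, seed=7)
        r2 = morans_i_permutation(grid4x4_rook, x, n_perm=199, seed=7)
        assert r1 == r2
        assert 0 < r1[1] <= 1
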