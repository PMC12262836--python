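"""Circuit solver against closed forms, dense pseudoinverse and Dijkstra
oracles; Kirchhoff/reciprocity/Rayleigh properties."""

import networkx as nx
import numpy as np
import pytest

from phckit.circuit import (
    ConnectivityError,
    build_graph,
    build_resistance,
    corridor_centrality,
    extract_corridor,
    solve_pair,
)
from phckit.raster import RasterGrid


def make_graph(res_values, cell=100.0, neighborhood=8, patches=None):
    """Graph over an explicit per-cell RESISTANCE array."""
    res_values = np.asarray(res_values, float)
    surface = build_resistance(RasterGrid(np.ones_like(res_values), cell))
    surface.grid.values[:] = res_values
    return build_graph(surface, neighborhood, patches)


class TestBuildResistance:
    def test_reciprocal_rule(self):
        s = RasterGrid(np.array([[1.0, 0.5, 0.0]]), 100.0)
        r = build_resistance(s, epsilon=1e-3).grid.values
        np.testing.assert_allclose(r, [[1.0, 2.0, 1000.0]])

    def test_out_of_range_suitability_rejected(self):
        with pytest.raises(ValueError):
            build_resistance(RasterGrid(np.array([[1.5]] * 2), 100.0))


class TestBuildGraph:
    def test_series_chain_two_unit_edges(self):
        g = make_graph(np.ones((1, 3)), neighborhood=4)
        assert g.n_nodes == 3
        assert len(g.edge_r) == 2
        np.testing.assert_allclose(g.edge_r, 1.0)

    def test_edge_resistance_is_mean_of_cells(self):
        g = make_graph(np.array([[1.0, 3.0]]), neighborhood=4)
        np.testing.assert_allclose(g.edge_r, [2.0])

    def test_diagonal_edge_scaled_by_sqrt2(self):
        g = make_graph(np.ones((2, 2)), neighborhood=8)
        diag = sorted(g.edge_r)[-2:]
        np.testing.assert_allclose(diag, np.sqrt(2.0))

    def test_harmonic_average_option(self):
        surface = build_resistance(RasterGrid(np.ones((1, 2)), 100.0))
        surface.grid.values[:] = [[1.0, 3.0]]
        g = build_graph(surface, 4, edge_average="harmonic")
        np.testing.assert_allclose(g.edge_r, [1.5])

    def test_patch_supernode_short_circuits_members(self):
        vals = np.ones((3, 5))
        patches = [np.array([[0, 0], [1, 0], [2, 0]])]
        g = make_graph(vals, neighborhood=4, patches=patches)
        assert g.n_nodes == 15 - 3 + 1
        assert len(g.patch_nodes) == 1


class TestSolvePair:
    def test_series_law(self):
        g = make_graph(np.ones((1, 3)), neighborhood=4)
        sol = solve_pair(g, 0, 2)
        assert sol.effective_resistance == pytest.approx(2.0)
        edge_cur = np.abs(sol.potentials[g.edge_u] - sol.potentials[g.edge_v]) / g.edge_r
        np.testing.assert_allclose(edge_cur, 1.0)

    def test_parallel_law(self):
        # two corner-to-corner 2-edge paths on a 2x2 orthogonal grid
        g = make_graph(np.ones((2, 2)), neighborhood=4)
        sol = solve_pair(g, 0, 3)
        assert sol.effective_resistance == pytest.approx(1.0)
        edge_cur = np.abs(sol.potentials[g.edge_u] - sol.potentials[g.edge_v]) / g.edge_r
        np.testing.assert_allclose(edge_cur, 0.5)

    def test_effective_resistance_matches_dense_pseudoinverse(self):
        rng = np.random.default_rng(0)
        g = make_graph(rng.uniform(0.5, 5.0, (5, 5)))
        Lp = np.linalg.pinv(g.laplacian().toarray(), rcond=1e-10)
        for a, b in [(0, 24), (3, 17), (10, 11)]:
            oracle = Lp[a, a] + Lp[b, b] - 2 * Lp[a, b]
            sol = solve_pair(g, a, b, with_current_map=False)
            assert sol.effective_resistance == pytest.approx(oracle, abs=1e-10)

    def test_matches_networkx_resistance_distance(self):
        rng = np.random.default_rng(1)
        g = make_graph(rng.uniform(0.5, 5.0, (4, 4)), neighborhood=4)
        G = nx.Graph()
        for u, v, r in zip(g.edge_u, g.edge_v, g.edge_r):
            G.add_edge(int(u), int(v), resistance=float(r))
        for a, b in [(0, 15), (5, 10)]:
            oracle = nx.resistance_distance(G, a, b, weight="resistance", invert_weight=True)
            sol = solve_pair(g, a, b, with_current_map=False)
            assert sol.effective_resistance == pytest.approx(oracle, rel=1e-10)

    def test_kirchhoff_and_reciprocity(self):
        rng = np.random.default_rng(2)
        g = make_graph(rng.uniform(0.2, 8.0, (6, 6)))
        ab = solve_pair(g, 2, 33)
        ba = solve_pair(g, 33, 2, with_current_map=False)
        assert ab.max_kirchhoff_residual < 1e-8
        assert ab.effective_resistance == pytest.approx(ba.effective_resistance, abs=1e-14)

    def test_same_terminal_rejected(self):
        g = make_graph(np.ones((2, 2)))
        with pytest.raises(ValueError):
            solve_pair(g, 1, 1)

    def test_disconnected_terminals_error(self):
        vals = np.ones((1, 5))
        grid = RasterGrid(vals, 100.0,
                          nodata_mask=np.array([[False, False, True, False, False]]))
        surface = build_resistance(grid)
        g = build_graph(surface, 4)
        with pytest.raises(ConnectivityError):
            solve_pair(g, 0, g.n_nodes - 1)

    def test_rayleigh_monotonicity_spot_check(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0.5, 4.0, (5, 5))
        g0 = make_graph(base)
        r0 = solve_pair(g0, 0, 24, with_current_map=False).effective_resistance
        for _ in range(10):
            bumped = base.copy()
            r, c = rng.integers(0, 5, 2)
            bumped[r, c] *= 1.0 + rng.uniform(0.1, 3.0)
            g1 = make_graph(bumped)
            r1 = solve_pair(g1, 0, 24, with_current_map=False).effective_resistance
            assert r1 >= r0 - 1e-12


class TestCorridors:
    def test_uniform_field_straight_path(self):
        vals = np.ones((9, 15))
        patches = [np.array([[4, 1]]), np.array([[4, 13]])]
        g = make_graph(vals, cell=300.0, patches=patches)
        geom = extract_corridor(g, 0, 1)
        assert geom.length_km == pytest.approx(12 * 0.3)
        assert geom.lcp_cost == pytest.approx(12.0)

    def test_zero_cutoff_keeps_only_lcp_cells(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.5, 5.0, (7, 7))
        patches = [np.array([[3, 0]]), np.array([[3, 6]])]
        g = make_graph(vals, patches=patches)
        geom = extract_corridor(g, 0, 1, cwd_cutoff=0.0)
        nc = 7
        on_path = set()
        for node in geom.lcp_nodes:
            cells = np.flatnonzero(g.cell_node == node)
            on_path.update((c // nc, c % nc) for c in cells)
        in_mask = {tuple(rc) for rc in np.argwhere(geom.corridor_mask)}
        assert on_path <= in_mask  # equality up to exact cost ties
        assert len(in_mask) <= len(on_path) + 2

    def test_low_resistance_channel_matches_dijkstra_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(2.0, 9.0, (7, 7))
        vals[3, :] = 0.5  # cheap channel
        patches = [np.array([[3, 0]]), np.array([[3, 6]])]
        g = make_graph(vals, patches=patches)
        geom = extract_corridor(g, 0, 1)
        G = nx.Graph()
        for u, v, r in zip(g.edge_u, g.edge_v, g.edge_r):
            G.add_edge(int(u), int(v), weight=float(r))
        oracle_cost = nx.dijkstra_path_length(G, g.patch_nodes[0], g.patch_nodes[1])
        assert geom.lcp_cost == pytest.approx(oracle_cost, rel=1e-12)

    def test_corridor_contains_lcp(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0.5, 5.0, (10, 10))
        patches = [np.array([[1, 1]]), np.array([[8, 8]])]
        g = make_graph(vals, patches=patches)
        geom = extract_corridor(g, 0, 1, cutoff_fraction=0.2)
        for node in geom.lcp_nodes:
            cells = np.flatnonzero(g.cell_node == node)
            for c in cells:
                assert geom.corridor_mask.ravel()[c]

    def test_no_path_raises(self):
        mask = np.zeros((3, 5), bool)
        mask[:, 2] = True
        grid = RasterGrid(np.ones((3, 5)), 100.0, nodata_mask=mask)
        g = build_graph(build_resistance(grid), 4,
                        patches=[np.array([[1, 0]]), np.array([[1, 4]])])
        with pytest.raises(ConnectivityError):
            extract_corridor(g, 0, 1)


class TestCentrality:
    def test_two_patches_single_link(self):
        cent = corridor_centrality(2, [(0, 1, 5.0)])
        assert cent[(0, 1)] == pytest.approx(1.0)

    def test_three_patch_line_hand_solved(self):
        cent = corridor_centrality(3, [(0, 1, 2.0), (1, 2, 3.0)])
        # tree network: each link carries full current for 2 of the 3 pairs
        assert cent[(0, 1)] == pytest.approx(2.0)
        assert cent[(1, 2)] == pytest.approx(2.0)

    def test_symmetric_cycle_equal_centrality(self):
        cent = corridor_centrality(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])
        vals = list(cent.values())
        np.testing.assert_allclose(vals, vals[0])

    def test_disconnected_network_warns(self):
        with pytest.warns(UserWarning, match="disconnected"):
            cent = corridor_centrality(4, [(0, 1, 1.0), (2, 3, 1.0)])
        assert cent[(0, 1)] == pytest.approx(1.0)

    def test_invalid_links_rejected(self):
        with pytest.raises(ValueError):
            corridor_centrality(2, [(0, 0, 1.0)])
        with pytest.raises(ValueError):
            corridor_centrality(2, [(0, 1, 0.0)])
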