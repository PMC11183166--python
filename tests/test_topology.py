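"""Graph thresholding, metrics, null models and AUC summaries."""

import numpy as np
import networkx as nx
import pytest

import morphnet as mn
from morphnet.topology import SparsityGrid, _cp_lp

from conftest import random_graph


def complete_graph(n):
    a = np.ones((n, n), dtype=np.uint8) - np.eye(n, dtype=np.uint8)
    return mn.BinaryGraph(adjacency=a)


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return mn.BinaryGraph(adjacency=a)


def floyd_warshall(a):
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return d


def oracle_metrics(g):
    """Brute-force recomputation of every metric from first principles."""
    a = g.adjacency.astype(int)
    n = a.shape[0]
    d = floyd_warshall(a)
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1), 0.0)
    np.fill_diagonal(inv, 0.0)
    nodal_eff = inv.sum(1) / (n - 1)
    eg = nodal_eff.mean()
    lp = np.inf if eg == 0 else 1.0 / eg
    cis = []
    elocs = []
    for i in range(n):
        nb = np.nonzero(a[i])[0]
        k = nb.size
        if k < 2:
            cis.append(0.0)
            continue
        links = sum(a[u, v] for ui, u in enumerate(nb) for v in nb[ui + 1:])
        cis.append(2.0 * links / (k * (k - 1)))
    for i in range(n):
        nb = np.nonzero(a[i])[0]
        if nb.size < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        ds = floyd_warshall(sub)
        invs = np.where(np.isfinite(ds) & (ds > 0), 1.0 / np.where(ds > 0, ds, 1), 0.0)
        np.fill_diagonal(invs, 0.0)
        elocs.append((invs.sum(1) / (nb.size - 1)).mean())
    return {
        "Cp": float(np.mean(cis)),
        "Lp": lp,
        "Eg": float(eg),
        "Eloc": float(np.sum(elocs) / n),
        "nodal_efficiency": nodal_eff,
    }


class TestThresholdBySparsity:
    def test_small_matrix_edge_count(self):
        rng = np.random.default_rng(0)
        w = rng.random((5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        g = mn.threshold_by_sparsity(w, 0.4)
        assert g.n_edges == 4  # floor(0.4 * 10)

    def test_full_parcellation_edge_count_matches_brute_force(self):
        rng = np.random.default_rng(1)
        w = rng.random((116, 116))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        g = mn.threshold_by_sparsity(w, 0.05)
        assert g.n_edges == 333  # floor(0.05 * 6670)
        # brute-force: count off-diagonal entries above the cutoff
        iu = np.triu_indices(116, 1)
        cutoff = np.sort(w[iu])[::-1][332]
        assert (w[iu] > cutoff).sum() <= 333 <= (w[iu] >= cutoff).sum()

    def test_saturation_and_zero_edge_error(self):
        w = np.ones((6, 6))
        g = mn.threshold_by_sparsity(w, 1.0)
        assert g.n_edges == 15 and g.sparsity == 1.0
        with pytest.raises(ValueError, match="0 of"):
            mn.threshold_by_sparsity(w, 0.01)

    def test_ties_broken_deterministically(self):
        w = np.full((6, 6), 0.5)
        np.fill_diagonal(w, 1.0)
        g1 = mn.threshold_by_sparsity(w, 0.3)
        g2 = mn.threshold_by_sparsity(w.copy(), 0.3)
        assert np.array_equal(g1.adjacency, g2.adjacency)
        # lexicographically first pairs retained
        assert g1.adjacency[0, 1] == 1 and g1.adjacency[0, 2] == 1

    def test_edge_sets_nest_across_thresholds(self, small_similarity):
        w = small_similarity[0]
        prev = None
        for s in SparsityGrid().thresholds[:10]:
            g = mn.threshold_by_sparsity(w, s)
            if prev is not None:
                assert np.all(g.adjacency >= prev)  # superset of edges
            prev = g.adjacency


class TestGlobalAndNodalMetrics:
    def test_complete_graph_metrics(self):
        gm = mn.clustering_and_paths(complete_graph(4))
        assert (gm.Cp, gm.Lp, gm.Eg, gm.Eloc) == (1.0, 1.0, 1.0, 1.0)

    def test_three_node_path_hand_values(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        gm = mn.clustering_and_paths(g)
        assert gm.Eg == pytest.approx(5 / 6)  # pairs: 1,1,1/2 -> mean 5/6
        assert gm.Lp == pytest.approx(6 / 5)
        assert gm.Cp == 0.0

    def test_star_graph_center_efficiency(self):
        g = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        gm = mn.clustering_and_paths(g)
        assert gm.Cp == 0.0
        assert gm.nodal_efficiency[0] == pytest.approx(1.0)

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            mn.clustering_and_paths(complete_graph(2))

    def test_betweenness_star_complete_and_ring(self):
        star = graph_from_edges(6, [(0, i) for i in range(1, 6)])
        b = mn.betweenness(star)
        assert b[0] == pytest.approx(10.0)  # all C(5,2) pairs via center
        assert np.allclose(b[1:], 0.0)
        assert np.allclose(mn.betweenness(complete_graph(5)), 0.0)
        ring = graph_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])
        b_nx = nx.betweenness_centrality(nx.cycle_graph(6), normalized=False)
        assert np.allclose(mn.betweenness(ring), [b_nx[i] for i in range(6)])

    def test_all_metrics_match_brute_force_oracle_on_random_graphs(self):
        """Floyd-Warshall-based recomputation on 200 small random graphs."""
        checked = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 13))
            g = random_graph(n, rng.uniform(0.2, 0.9), seed)
            want = oracle_metrics(g)
            got = mn.clustering_and_paths(g)
            assert got.Cp == pytest.approx(want["Cp"], abs=1e-12)
            assert got.Eg == pytest.approx(want["Eg"], abs=1e-12)
            assert got.Eloc == pytest.approx(want["Eloc"], abs=1e-12)
            if np.isfinite(want["Lp"]):
                assert got.Lp == pytest.approx(want["Lp"], abs=1e-12)
            assert np.allclose(got.nodal_efficiency, want["nodal_efficiency"],
                               atol=1e-12)
            gx = nx.from_numpy_array(g.adjacency)
            b_nx = nx.betweenness_centrality(gx, normalized=False)
            assert np.allclose(mn.betweenness(g), [b_nx[i] for i in range(n)],
                               atol=1e-9)
            checked += 1
        assert checked == 200


class TestNullModelAndSmallWorld:
    def test_rewiring_preserves_degree_sequence(self):
        for seed in range(5):
            g = random_graph(30, 0.2, 100 + seed)
            null = mn.rewired_null(g, seed=seed)
            assert np.array_equal(null.degrees, g.degrees)
            assert null.n_edges == g.n_edges
            assert not np.any(np.diag(null.adjacency))

    def test_rewiring_actually_randomizes(self):
        g = random_graph(40, 0.15, 7)
        null = mn.rewired_null(g, seed=1)
        assert not np.array_equal(null.adjacency, g.adjacency)

    def test_complete_graph_cannot_be_rewired(self):
        g = complete_graph(6)
        null = mn.rewired_null(g, seed=0)
        assert np.array_equal(null.adjacency, g.adjacency)

    def test_ring_lattice_loses_clustering_under_rewiring(self):
        gx = nx.watts_strogatz_graph(50, 4, 0.0, seed=0)  # pure lattice
        g = mn.BinaryGraph(adjacency=nx.to_numpy_array(gx, dtype=int))
        cp_lattice, _ = _cp_lp(g.adjacency)
        null_cps = [_cp_lp(mn.rewired_null(g, seed=s).adjacency)[0] for s in range(20)]
        assert np.mean(null_cps) < cp_lattice

    def test_complete_graph_normalizes_to_unity(self):
        gamma, lam, sigma = mn.small_world(complete_graph(8), n_null=5, seed=0)
        assert (gamma, lam, sigma) == (1.0, 1.0, 1.0)

    def test_watts_strogatz_ring_is_small_world(self):
        gx = nx.watts_strogatz_graph(100, 6, 0.05, seed=1)
        g = mn.BinaryGraph(adjacency=nx.to_numpy_array(gx, dtype=int))
        gamma, lam, sigma = mn.small_world(g, n_null=20, seed=2)
        assert gamma > 1.0
        assert sigma == pytest.approx(gamma / lam)


class TestCurvesAndAUC:
    def test_default_grid_has_36_thresholds(self):
        grid = SparsityGrid()
        assert len(grid) == 36
        assert grid.thresholds[0] == pytest.approx(0.05)
        assert grid.thresholds[-1] == pytest.approx(0.40)

    def test_metric_curves_shapes_and_monotone_degree(self, small_similarity):
        w = small_similarity[0]
        grid = SparsityGrid(start=0.2, stop=0.4, step=0.05)
        gdf, ndf = mn.metric_curves(w, grid=grid, n_null=5, seed=0,
                                    subject_id="s0")
        assert len(gdf) == len(grid)
        assert len(ndf) == len(grid) * w.n_regions
        assert np.allclose(gdf["sigma"], gdf["gamma"] / gdf["lambda"])
        for _, sub in ndf.groupby("node"):
            deg = sub.sort_values("threshold")["degree"].to_numpy()
            assert (np.diff(deg) >= 0).all()

    def test_auc_constant_linear_and_random_curves(self):
        grid = SparsityGrid()
        assert mn.auc(np.full(36, 2.0), grid) == pytest.approx(0.7)
        assert mn.auc(np.linspace(0, 1, 36), grid) == pytest.approx(0.175)
        rng = np.random.default_rng(0)
        curve = rng.random(36)
        t = grid.thresholds
        oracle = sum(
            (curve[i] + curve[i + 1]) / 2 * (t[i + 1] - t[i]) for i in range(35)
        )
        assert mn.auc(curve, grid) == pytest.approx(oracle, abs=1e-12)

    def test_auc_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            mn.auc(np.ones(10), SparsityGrid())


class TestThresholdProperties:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(5, 25), s=st.floats(0.05, 1.0), seed=st.integers(0, 10_000))
    def test_edge_count_formula_holds_for_any_matrix(self, n, s, seed):
        rng = np.random.default_rng(seed)
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        k = int(np.floor(s * n * (n - 1) / 2))
        if k == 0:
            with pytest.raises(ValueError):
                mn.threshold_by_sparsity(w, s)
        else:
            g = mn.threshold_by_sparsity(w, s)
            assert g.n_edges == k
            assert not np.any(np.diag(g.adjacency))

    @settings(max_examples=15, deadline=None)
    @given(n=st.integers(6, 20), seed=st.integers(0, 10_000))
    def test_stronger_thresholds_nest(self, n, seed):
        rng = np.random.default_rng(seed)
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        sparse = mn.threshold_by_sparsity(w, 0.2).adjacency
        dense = mn.threshold_by_sparsity(w, 0.6).adjacency
        assert np.all(dense >= sparse)
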