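import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphnet.topology import (
    BinaryGraph,
    characteristic_path_length,
    clustering_coefficient,
    curve_auc,
    max_edges,
    min_estimable_sparsity,
    normalized_small_world,
    proportional_threshold,
    rewire_preserving_degree,
    sparsity_sweep,
)


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryGraph(a)


def brute_force_clustering(a):
    """Triangle count by explicit triple enumeration."""
    n = a.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(a[u, v] for u, v in itertools.combinations(nbrs, 2))
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def brute_force_path_length(a):
    """BFS from every node; mean over reachable unordered pairs."""
    n = a.shape[0]
    dists = []
    for src in range(n):
        seen = {src: 0}
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if a[u, v] and v not in seen:
                        seen[v] = d
                        nxt.append(v)
            frontier = nxt
        dists.extend(seen[v] for v in seen if v > src)
    return float(np.mean(dists)) if dists else float("nan")


class TestCounting:
    @pytest.mark.parametrize("n,expected", [(58, 1653), (62, 1891), (2, 1)])
    def test_max_edges(self, n, expected):
        assert max_edges(n) == expected

    @pytest.mark.parametrize(
        "n,expected", [(58, 0.071), (62, 0.068), (10, 0.256)]
    )
    def test_min_estimable_sparsity(self, n, expected):
        assert min_estimable_sparsity(n) == expected


class TestProportionalThreshold:
    def test_keeps_exactly_the_largest_edges(self, rng):
        w = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        weights = rng.permutation([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        w[iu] = weights
        w += w.T
        g = proportional_threshold(w, 2 / 6)
        kept = {tuple(sorted(e)) for e in zip(*np.nonzero(np.triu(g.adjacency)))}
        order = np.argsort(-weights)
        expected = {tuple(sorted((iu[0][k], iu[1][k]))) for k in order[:2]}
        assert kept == expected

    def test_full_sparsity_gives_complete_graph(self, rng):
        w = rng.random((5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        g = proportional_threshold(w, 1.0)
        assert g.n_edges == max_edges(5)

    def test_tied_weights_deterministic(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0)
        a = proportional_threshold(w, 0.5)
        b = proportional_threshold(w, 0.5)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_nested_sparsities_give_nested_edge_sets(self, rng):
        w = rng.random((12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        prev = None
        for s in (0.1, 0.2, 0.4, 0.8):
            g = proportional_threshold(w, s)
            if prev is not None:
                assert np.all(g.adjacency >= prev)
            prev = g.adjacency

    def test_zero_edge_sparsity_rejected(self):
        w = np.eye(4) * 0
        with pytest.raises(ValueError, match="zero edges"):
            proportional_threshold(w, 1e-4)


class TestSmallWorldMetrics:
    def test_complete_and_star_clustering(self):
        k4 = graph_from_edges(4, itertools.combinations(range(4), 2))
        assert clustering_coefficient(k4) == 1.0
        star = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert clustering_coefficient(star) == 0.0

    def test_five_node_clustering_hand_value(self):
        g = graph_from_edges(5, [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)])
        assert clustering_coefficient(g) == pytest.approx(0.4667, abs=1e-4)

    def test_path_graph_path_length(self):
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        lp, disconnected = characteristic_path_length(g)
        assert lp == pytest.approx(10 / 6)
        assert not disconnected

    def test_complete_graph_path_length_one(self):
        k4 = graph_from_edges(4, itertools.combinations(range(4), 2))
        assert characteristic_path_length(k4) == (1.0, False)

    def test_disconnected_components_flagged(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        lp, disconnected = characteristic_path_length(g)
        assert lp == 1.0
        assert disconnected

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError, match="edgeless"):
            characteristic_path_length(BinaryGraph(np.zeros((3, 3), dtype=int)))

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**10 - 1))
    def test_metrics_match_brute_force_on_five_node_graphs(self, bits):
        iu = np.triu_indices(5, 1)
        a = np.zeros((5, 5), dtype=int)
        mask = [(bits >> k) & 1 for k in range(10)]
        a[iu] = mask
        a += a.T
        g = BinaryGraph(a)
        assert clustering_coefficient(g) == pytest.approx(
            brute_force_clustering(a), abs=1e-12
        )
        if a.sum() > 0:
            lp, _ = characteristic_path_length(g)
            assert lp == pytest.approx(brute_force_path_length(a), abs=1e-12)


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        for _ in range(10):
            a = (rng.random((12, 12)) < 0.3).astype(int)
            a = np.triu(a, 1)
            a += a.T
            g = BinaryGraph(a)
            if g.n_edges < 2:
                continue
            null = rewire_preserving_degree(g, n_swaps=10 * g.n_edges, seed=0)
            assert np.array_equal(
                np.sort(null.degrees), np.sort(g.degrees)
            )

    def test_complete_graph_returned_unchanged_with_warning(self):
        k4 = graph_from_edges(4, itertools.combinations(range(4), 2))
        with pytest.warns(UserWarning, match="fell back"):
            null = rewire_preserving_degree(k4, n_swaps=5, seed=0)
        assert np.array_equal(null.adjacency, k4.adjacency)

    def test_same_seed_reproducible(self, rng):
        a = (rng.random((14, 14)) < 0.3).astype(int)
        a = np.triu(a, 1)
        a += a.T
        g = BinaryGraph(a)
        x = rewire_preserving_degree(g, 50, seed=3)
        y = rewire_preserving_degree(g, 50, seed=3)
        assert np.array_equal(x.adjacency, y.adjacency)


class TestNormalizedSmallWorld:
    def test_ring_lattice_has_high_normalized_clustering(self):
        g = BinaryGraph(
            nx.to_numpy_array(nx.watts_strogatz_graph(60, 6, 0.0), dtype=int)
        )
        gamma, _ = normalized_small_world(g, n_null=20, seed=0)
        assert gamma > 1.0

    def test_dense_random_graph_is_its_own_null(self, rng):
        # an ER-like graph should be statistically indistinguishable from
        # its rewired ensemble
        for seed in range(5):
            a = (np.random.default_rng(seed).random((40, 40)) < 0.3).astype(int)
            a = np.triu(a, 1)
            a += a.T
            gamma, lam = normalized_small_world(BinaryGraph(a), n_null=20, seed=seed)
            assert gamma == pytest.approx(1.0, abs=0.15)
            assert lam == pytest.approx(1.0, abs=0.15)


class TestSparsitySweep:
    def test_default_range_has_17_thresholds(self, rng):
        # block-community weights: clustered at every sparsity, and dense
        # enough that rewired nulls keep nonzero clustering, so all curves
        # (including the normalized ones) stay finite
        n = 40
        blocks = np.repeat(np.arange(5), 8)
        w = np.where(blocks[:, None] == blocks[None, :], 0.6, 0.1)
        w = w + 0.3 * rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        res = sparsity_sweep(w, n_null=5, seed=0)
        assert res.sparsities.size == 17
        assert res.sparsities[0] == 0.08 and res.sparsities[-1] == 0.40
        for curve in (res.cp, res.lp, res.gamma, res.lam):
            assert np.all(np.isfinite(curve))

    def test_path_length_non_increasing_with_density(self, rng):
        # nested edge sets: adding edges cannot lengthen shortest paths
        w = rng.random((25, 25))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        res = sparsity_sweep(w, n_null=2, seed=0)
        connected = ~res.disconnected
        lp = res.lp[connected]
        assert np.all(np.diff(lp) <= 1e-12)


class TestCurveAuc:
    def test_constant_curve(self):
        s = np.arange(0.08, 0.41, 0.02)
        assert curve_auc(np.ones_like(s), s) == pytest.approx(0.32)

    def test_linear_curve(self):
        s = np.linspace(0, 1, 11)
        assert curve_auc(s, s) == pytest.approx(0.5)

    def test_matches_manual_trapezoid(self, rng):
        s = np.sort(rng.random(5))
        s[1:] += np.arange(1, 5) * 1e-3  # ensure strictly increasing
        v = rng.random(5)
        manual = sum(
            (v[i] + v[i + 1]) / 2 * (s[i + 1] - s[i]) for i in range(4)
        )
        assert curve_auc(v, s) == pytest.approx(manual, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            curve_auc(np.array([1.0]), np.array([0.1]))
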