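import numpy as np
import pandas as pd
import pytest

from morphnet.association import (
    NonIdentifiableError,
    bh_fdr,
    edge_matrix,
    edgewise_correlation,
    estimate_variance_explained,
    permutation_pvalue_V,
    standardize_and_aggregate,
    subject_similarity_matrix,
)
from morphnet.network import MorphNetwork
from morphnet.simulate import simulate_behavior


def random_networks(rng, n_subjects, n_gyral=4, n_sulcal=4):
    """Subjects with fully independent random similarity structure."""
    n = n_gyral + n_sulcal
    classes = np.array(["gyral"] * n_gyral + ["sulcal"] * n_sulcal, dtype="U7")
    nets = []
    for _ in range(n_subjects):
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        nets.append(
            MorphNetwork(weights=w, region_ids=np.arange(n), classes=classes)
        )
    return nets


class TestStandardizeAndAggregate:
    def test_single_item_domain_equals_item_zscore(self, rng):
        raw = pd.DataFrame({"a": rng.normal(5, 2, 30)})
        table = standardize_and_aggregate(raw, {"a": "dom"})
        np.testing.assert_allclose(table.domains["dom"], table.items["a"])
        assert table.items["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert table.items["a"].std(ddof=1) == pytest.approx(1.0)

    def test_duplicate_items_do_not_change_domain_score(self, rng):
        x = rng.normal(size=25)
        one = standardize_and_aggregate(pd.DataFrame({"a": x}), {"a": "d"})
        two = standardize_and_aggregate(
            pd.DataFrame({"a": x, "b": x}), {"a": "d", "b": "d"}
        )
        np.testing.assert_allclose(one.domains["d"], two.domains["d"])

    def test_sixty_items_six_domains(self, rng):
        raw = pd.DataFrame(rng.normal(size=(40, 60)), columns=[f"i{k}" for k in range(60)])
        dmap = {f"i{k}": f"dom{k % 6}" for k in range(60)}
        table = standardize_and_aggregate(raw, dmap)
        assert table.domains.shape == (40, 6)

    def test_zero_variance_item_dropped_with_warning(self, rng):
        raw = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        with pytest.warns(UserWarning, match="zero-variance"):
            table = standardize_and_aggregate(raw, {"a": "d", "b": "d"})
        assert table.dropped_items == ["b"]

    def test_unmapped_item_rejected(self, rng):
        raw = pd.DataFrame({"a": rng.normal(size=20)})
        with pytest.raises(ValueError, match="without a domain"):
            standardize_and_aggregate(raw, {})


class TestSubjectSimilarity:
    def test_symmetric_unit_diagonal(self, rng):
        nets = random_networks(rng, 12)
        sim = subject_similarity_matrix(nets)
        assert np.array_equal(sim.m, sim.m.T)
        np.testing.assert_array_equal(np.diag(sim.m), 1.0)
        assert np.all(np.abs(sim.m) <= 1.0 + 1e-12)

    def test_duplicated_subject_perfectly_similar(self, rng):
        nets = random_networks(rng, 10)
        nets.append(
            MorphNetwork(
                weights=nets[0].weights.copy(),
                region_ids=nets[0].region_ids,
                classes=nets[0].classes,
            )
        )
        sim = subject_similarity_matrix(nets)
        assert sim.m[0, -1] == pytest.approx(1.0)

    def test_independent_networks_have_weak_similarity(self, rng):
        nets = random_networks(rng, 50, n_gyral=8, n_sulcal=8)
        sim = subject_similarity_matrix(nets)
        off = sim.m[np.triu_indices(50, 1)]
        assert np.abs(off).mean() < 0.2


class TestVarianceComponents:
    def _correlation_m(self, rng, n):
        m = np.corrcoef(rng.normal(size=(n, 40)))
        np.fill_diagonal(m, 1.0)
        return m

    def test_identity_m_not_identifiable(self, rng):
        y = rng.normal(size=(30, 2))
        with pytest.raises(NonIdentifiableError):
            estimate_variance_explained(y, np.eye(30))

    def test_unclamped_components_conserve_total_variance(self, rng):
        # with unit diagonal M, the second trace equation forces
        # sigma_b + sigma_e = y'y / n exactly, before clamping
        m = self._correlation_m(rng, 40)
        y = rng.normal(size=(40, 3))
        est = estimate_variance_explained(y, m)
        yc = y - y.mean(axis=0)
        total = (yc**2).sum(axis=0) / 40
        np.testing.assert_allclose(
            est.sigma_b_raw + est.sigma_e_raw, total, rtol=1e-10
        )

    def test_v_invariant_to_common_rescaling(self, rng):
        m = self._correlation_m(rng, 50)
        y = rng.normal(size=(50, 4))
        v1 = estimate_variance_explained(y, m).v
        v2 = estimate_variance_explained(y * 7.3, m).v
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_recovery_of_known_variance_fraction(self, rng):
        m = self._correlation_m(rng, 200)
        for v_true in (0.0, 0.5):
            estimates = [
                estimate_variance_explained(
                    simulate_behavior(m, 6, v_true, seed=s).to_numpy(), m
                ).v
                for s in range(8)
            ]
            assert np.mean(estimates) == pytest.approx(v_true, abs=0.1)


class TestPermutationPvalue:
    def test_strong_signal_hits_floor(self, rng):
        m = np.corrcoef(rng.normal(size=(200, 40)))
        np.fill_diagonal(m, 1.0)
        y = simulate_behavior(m, 4, v_true=0.8, seed=1).to_numpy()
        p = permutation_pvalue_V(y, m, n_perm=200, seed=0)
        assert p == pytest.approx(1 / 201)

    def test_same_seed_reproducible(self, rng):
        m = np.corrcoef(rng.normal(size=(40, 30)))
        np.fill_diagonal(m, 1.0)
        y = rng.normal(size=(40, 3))
        assert permutation_pvalue_V(y, m, 100, seed=5) == permutation_pvalue_V(
            y, m, 100, seed=5
        )


class TestBhFdr:
    def test_step_up_hand_example(self):
        sig, adj = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        assert list(sig) == [True, True, True, False]

    def test_all_tiny_pvalues_significant(self):
        sig, _ = bh_fdr(np.full(6, 0.001), q=0.05)
        assert sig.all()

    def test_empty_input(self):
        sig, adj = bh_fdr(np.array([]))
        assert sig.size == 0 and adj.size == 0

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            sig, adj = bh_fdr(p, q=0.05)
            ref_sig, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.array_equal(sig, ref_sig)
            np.testing.assert_allclose(adj, ref_adj, atol=1e-12)


class TestEdgewiseCorrelation:
    def test_edge_equal_to_score_has_unit_correlation(self, rng):
        score = rng.normal(size=20)
        edges = np.column_stack([score, rng.normal(size=20)])
        res = edgewise_correlation(edges, score)
        assert res.r[0] == pytest.approx(1.0)
        assert res.p[0] == 0.0

    def test_matches_brute_force_pearson(self, rng):
        edges = rng.normal(size=(4, 5))
        score = rng.normal(size=4)
        res = edgewise_correlation(edges, score)
        for j in range(5):
            x, y = edges[:, j], score
            r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert res.r[j] == pytest.approx(r, abs=1e-12)

    def test_constant_edge_excluded_with_warning(self, rng):
        edges = np.column_stack([np.ones(10), rng.normal(size=10)])
        with pytest.warns(UserWarning, match="constant edge"):
            res = edgewise_correlation(edges, rng.normal(size=10))
        assert np.isnan(res.r[0]) and not res.significant[0]

    def test_node_counts_attribute_edges_to_endpoints(self, rng):
        score = rng.normal(size=30)
        edges = np.column_stack([score, score, rng.normal(size=30)])
        pairs = np.array([[0, 1], [1, 2], [2, 3]])
        res = edgewise_correlation(edges, score, edge_pairs=pairs, n_nodes=4)
        assert list(res.node_counts) == [1, 2, 1, 0]

    def test_edge_matrix_stacks_subject_vectors(self, rng):
        nets = random_networks(rng, 5, n_gyral=3, n_sulcal=3)
        em = edge_matrix(nets, block="gg")
        assert em.shape == (5, 3)
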