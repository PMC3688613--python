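"""Mixed-membership block model: likelihood, optimizer, model selection."""

import numpy as np
import networkx as nx
import pytest
from scipy.stats import spearmanr

from matenet import csbm
from matenet.csbm import (aic, edge_probability, fit_csbm, log_likelihood,
                          project_simplex_rows, sample_network, scan_models)


def _B3(b11, b22, b12=0.0):
    return np.array([[0, 0, 0], [0, b11, b12], [0, b12, b22]], dtype=float)


class TestEdgeProbability:
    def test_pure_nodes_pick_one_entry(self):
        B = _B3(0.4, 0.4, 0.01)
        assert edge_probability([0, 1, 0], [0, 0, 1], B) == pytest.approx(0.01)

    def test_pure_zero_ehn_disconnected(self):
        assert edge_probability([1, 0, 0], [1, 0, 0], _B3(0.9, 0.9)) == 0.0

    def test_mixture_bilinear_form(self):
        B = _B3(0.4, 0.4, 0.0)
        u = [0, 0.5, 0.5]
        assert edge_probability(u, u, B) == pytest.approx(0.2)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            edge_probability([1, 0], [1, 0, 0], _B3(0.5, 0.5))


class TestLogLikelihood:
    def test_single_edge(self):
        g = nx.Graph([("a", "b")])
        U = np.array([[0.0, 1.0], [0.0, 1.0]])
        B = np.array([[0.0, 0.0], [0.0, 0.5]])
        assert log_likelihood(g, U, B) == pytest.approx(np.log(0.5))

    def test_three_nodes_three_pairs(self):
        g = nx.Graph([("a", "b")])
        g.add_node("c")
        U = np.tile([0.0, 1.0], (3, 1))
        B = np.array([[0.0, 0.0], [0.0, 0.5]])
        assert log_likelihood(g, U, B) == pytest.approx(3 * np.log(0.5))

    def test_empty_network_pure_zero_ehn(self):
        g = nx.empty_graph(6)
        U = np.tile([1.0, 0.0], (6, 1))
        B = np.array([[0.0, 0.0], [0.0, 0.9]])
        assert log_likelihood(g, U, B) == pytest.approx(0.0, abs=1e-6)


class TestSimplexProjection:
    def test_rows_land_on_simplex(self, rng):
        V = rng.normal(0, 2, size=(50, 4))
        P = project_simplex_rows(V)
        assert np.all(P >= 0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_already_on_simplex_unchanged(self):
        V = np.array([[0.2, 0.3, 0.5]])
        np.testing.assert_allclose(project_simplex_rows(V), V)


class TestFit:
    def test_complete_graph_saturates(self):
        f = fit_csbm(nx.complete_graph(4), 2, n_restarts=3, seed=0)
        assert f.logL >= -0.01

    def test_empty_graph_all_zero_ehn(self):
        f = fit_csbm(nx.empty_graph(6), 2, n_restarts=3, seed=0)
        assert f.logL >= -0.01

    def test_two_cliques_recovered_exactly(self):
        from matenet.classify import classify_memberships

        g = nx.disjoint_union(nx.complete_graph(10), nx.complete_graph(10))
        f = fit_csbm(g, 3, n_restarts=10, seed=1)
        labels = classify_memberships(f)
        lab = labels["label"]
        first = list(range(10))
        second = list(range(10, 20))
        assert len(set(lab[first])) == 1 and len(set(lab[second])) == 1
        assert set(lab) == {"S1", "S2"}

    def test_invariants_of_fit(self):
        g = nx.gnp_random_graph(15, 0.3, seed=3)
        f = fit_csbm(g, 3, n_restarts=3, seed=3)
        np.testing.assert_allclose(f.U.sum(axis=1), 1.0, atol=1e-8)
        assert f.U.min() >= 0
        np.testing.assert_allclose(f.B, f.B.T, atol=1e-12)
        assert np.all(f.B[0, :] == 0) and np.all(f.B[:, 0] == 0)
        assert 0 <= f.B.min() and f.B.max() <= 1

    def test_monotone_ascent_trace(self):
        g = nx.gnp_random_graph(12, 0.4, seed=4)
        f = fit_csbm(g, 2, n_restarts=1, seed=4, trace=True)
        diffs = np.diff(f.trace)
        assert np.all(diffs >= -1e-9)

    def test_permutation_invariance(self):
        g = nx.gnp_random_graph(14, 0.35, seed=5)
        relabeled = nx.relabel_nodes(g, {i: f"z{99 - i}" for i in g.nodes()})
        f1 = fit_csbm(g, 2, n_restarts=5, seed=6)
        f2 = fit_csbm(relabeled, 2, n_restarts=5, seed=6)
        assert f1.logL == pytest.approx(f2.logL, abs=0.5)
        assert f1.aic == pytest.approx(f2.aic, abs=1.0)

    def test_low_degree_nodes_load_on_zero_ehn(self):
        """EHN 0 membership absorbs degree heterogeneity."""
        rng = np.random.default_rng(8)
        n = 80
        w = rng.uniform(0.05, 0.95, size=n)
        U = np.stack([1 - w, w], axis=1)
        B = np.array([[0.0, 0.0], [0.0, 0.5]])
        ids = [f"v{i:02d}" for i in range(n)]
        g = sample_network(ids, U, B, seed=9)
        f = fit_csbm(g, 2, n_restarts=5, seed=9)
        deg = np.array([g.degree(i) for i in f.ids])
        rho, _ = spearmanr(deg, f.U[:, 0])
        assert rho < -0.5

    def test_q_below_two_rejected(self):
        with pytest.raises(ValueError):
            fit_csbm(nx.complete_graph(4), 1, seed=0)

    def test_overparameterized_warns(self):
        with pytest.warns(UserWarning, match="over-parameterized"):
            fit_csbm(nx.complete_graph(3), 4, n_restarts=1, seed=0)

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(12, 0.4, seed=10)
        f1 = fit_csbm(g, 3, n_restarts=3, seed=11)
        f2 = fit_csbm(g, 3, n_restarts=3, seed=11)
        np.testing.assert_array_equal(f1.U, f2.U)
        np.testing.assert_array_equal(f1.B, f2.B)
        assert f1.logL == f2.logL


class TestAic:
    def test_formula_at_stand_scale(self):
        f = csbm.CSBMFit(Q=3, ids=[], U=np.zeros((0, 3)), B=np.zeros((3, 3)),
                         logL=-1000.0, aic=0.0, n_restarts_used=0,
                         best_restart_seed=0, converged=True, n_iter=0)
        assert aic(f, 206) == pytest.approx(2000.0 + 830.0)

    def test_zero_loglik_counts_parameters(self):
        f = csbm.CSBMFit(Q=2, ids=[], U=np.zeros((0, 2)), B=np.zeros((2, 2)),
                         logL=0.0, aic=0.0, n_restarts_used=0,
                         best_restart_seed=0, converged=True, n_iter=0)
        assert aic(f, 10) == pytest.approx(22.0)


class TestScan:
    def test_single_clique_penalty_favors_q2(self):
        g = nx.complete_graph(10)
        diffs = []
        for seed in range(5):
            scan = scan_models(g, 2, 3, n_restarts=4, seed=seed)
            diffs.append(scan.fits[2].aic - scan.fits[3].aic)
        assert np.mean(diffs) <= 0

    def test_override_recorded_and_ranking_kept(self):
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
        scan = scan_models(g, 2, 4, override_Q=3, n_restarts=3, seed=2)
        assert scan.selected_Q == 3
        assert scan.override_Q == 3
        assert scan.ranking == sorted(scan.fits, key=lambda q: scan.fits[q].aic)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            scan_models(nx.complete_graph(4), 1, 3)
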