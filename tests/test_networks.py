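"""Joint graphical lasso solver, eBIC selection and network summaries:
oracle equivalence with a single-matrix reference, solver invariants, and
brute-force betweenness recounts."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.covariance import graphical_lasso

from mbstage import networks, synthetic
from oracles import betweenness_brute


def _random_corr(p, n, seed):
    rng = np.random.default_rng(seed)
    prec = synthetic.make_sparse_precision(p, max(1, p // 2), seed=seed)
    x = rng.multivariate_normal(np.zeros(p), np.linalg.inv(prec), size=n)
    z = (x - x.mean(0)) / x.std(0)
    return z.T @ z / n


class TestSectionCovariances:
    def test_unit_diagonal(self, rng):
        secs = [pd.DataFrame(rng.normal(size=(30, 4)))]
        covs, ns = networks.section_covariances(secs)
        np.testing.assert_allclose(np.diag(covs[0]), 1.0, atol=1e-12)
        assert ns == [30]

    def test_perfect_correlation(self):
        a = np.arange(12.0)
        sec = pd.DataFrame({"x": a, "y": 2 * a + 1, "z": np.r_[a[:6], -a[:6]]})
        covs, _ = networks.section_covariances([sec])
        assert covs[0][0, 1] == pytest.approx(1.0)

    def test_matches_hand_correlation(self):
        sec = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 8, 2, 1, 0, 4],
                            "b": [2.0, 1, 4, 3, 7, 2, 2, 5, 1, 0],
                            "c": [5.0, 4, 3, 2, 1, 0, 2, 4, 6, 8]})
        covs, _ = networks.section_covariances([sec])
        x = sec.to_numpy()
        zx = (x - x.mean(0)) / x.std(0)
        expected = zx.T @ zx / 10
        np.testing.assert_allclose(covs[0], expected, atol=1e-12)

    def test_zero_variance_metabolite_named(self):
        sec = pd.DataFrame({"ok": np.arange(10.0), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            networks.section_covariances([sec])


class TestGroupGraphicalLasso:
    def test_huge_lambda1_gives_diagonal(self):
        covs = [_random_corr(5, 200, 0), _random_corr(5, 200, 1)]
        sol = networks.group_graphical_lasso(covs, [200, 200], 10.0, 0.01)
        for sup in sol.supports():
            assert sup.sum() == 0

    def test_single_section_matches_reference_glasso(self):
        """K=1, lambda2=0 reduces to the standard graphical lasso."""
        for seed in range(10):
            s = _random_corr(4, 300, seed)
            sol = networks.group_graphical_lasso(
                [s], [300], 0.1, 0.0,
                networks.GGLConfig(tol=1e-8, max_iter=5000))
            # the reference needs tight inner/outer tolerances to resolve
            # entries near the soft-threshold boundary
            _, ref = graphical_lasso(s, alpha=0.1, tol=1e-10, enet_tol=1e-12,
                                     max_iter=2000)
            np.testing.assert_allclose(sol.precisions[0], ref, atol=1e-4)

    def test_large_lambda2_shares_supports(self):
        covs = [_random_corr(6, 150, s) for s in range(3)]
        sol = networks.group_graphical_lasso(
            covs, [150] * 3, 0.05, 100.0,
            networks.GGLConfig(tol=1e-7, max_iter=3000))
        sups = sol.supports()
        for s in sups[1:]:
            np.testing.assert_array_equal(s, sups[0])

    def test_solutions_symmetric_positive_definite(self):
        covs = [_random_corr(6, 100, s) for s in range(2)]
        sol = networks.group_graphical_lasso(covs, [100, 100], 0.1, 0.02)
        for theta in sol.precisions:
            assert np.abs(theta - theta.T).max() < 1e-10
            assert np.linalg.eigvalsh(theta).min() > 0

    def test_edge_count_monotone_in_lambda1(self):
        covs = [_random_corr(8, 400, 7)]
        counts = []
        for l1 in (0.05, 0.1, 0.15, 0.2, 0.25):
            sol = networks.group_graphical_lasso(covs, [400], l1, 0.01)
            counts.append(int(sol.supports()[0].sum()))
        assert counts == sorted(counts, reverse=True)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            networks.group_graphical_lasso([np.eye(3), np.eye(4)], [50, 50], 0.1, 0.01)


class TestEbic:
    def _single_solution(self, theta, s, n):
        sup = np.abs(theta) > 1e-5
        return networks.GGLSolution(
            precisions=[theta], sparse_precisions=[theta], covariances=[s],
            n_obs=[n], lambda1=0.1, lambda2=0.01, iterations=1, converged=True)

    def test_hand_calculation_2x2(self):
        theta = np.array([[2.0, 0.5], [0.5, 1.5]])
        s = np.array([[1.0, 0.3], [0.3, 1.0]])
        n = 50
        sol = self._single_solution(theta, s, n)
        ll = n * (np.trace(s @ theta) - np.log(np.linalg.det(theta)))
        expected = ll + 1 * np.log(n) + 4 * 20 * 1 * np.log(2)
        assert networks.ebic(sol, gamma=20.0) == pytest.approx(expected, abs=1e-10)

    def test_gamma_zero_reduces_to_bic(self):
        theta = np.array([[2.0, 0.5], [0.5, 1.5]])
        s = np.array([[1.0, 0.3], [0.3, 1.0]])
        sol = self._single_solution(theta, s, 50)
        ll = 50 * (np.trace(s @ theta) - np.log(np.linalg.det(theta)))
        assert networks.ebic(sol, gamma=0.0) == pytest.approx(ll + np.log(50))

    def test_extra_edge_with_negligible_gain_increases_score(self):
        s = np.array([[1.0, 0.001], [0.001, 1.0]])
        diag = np.diag(1.0 / np.diag(s))
        with_edge = np.array([[1.0, -0.001], [-0.001, 1.0]])
        sol_diag = self._single_solution(diag, s, 100)
        sol_edge = self._single_solution(with_edge, s, 100)
        assert networks.ebic(sol_edge, 20.0) > networks.ebic(sol_diag, 20.0)


class TestSweepAndSelect:
    def test_single_pair_grid_trivially_selected(self):
        covs = [_random_corr(5, 200, 3)]
        config = networks.GGLConfig(lambda1_grid=(0.1,), lambda2_grid=(0.01,))
        best, table = networks.sweep_and_select(covs, [200], config)
        assert (best.lambda1, best.lambda2) == (0.1, 0.01)
        assert len(table) == 1

    def test_score_table_covers_grid(self):
        covs = [_random_corr(5, 200, 4)]
        config = networks.GGLConfig(lambda1_grid=(0.1, 0.2), lambda2_grid=(0.01, 0.02))
        _, table = networks.sweep_and_select(covs, [200], config)
        assert len(table) == 4
        assert table.converged.all()

    def test_planted_shared_precision_recovered(self):
        """eBIC-selected solution recovers the planted edge set."""
        from oracles import edge_f1
        # disjoint-pair truth with strong partial correlations (0.7): under
        # the sparsity-forcing eBIC gamma only such edges are identifiable
        prec = synthetic.make_sparse_precision(10, 5, value=0.7, margin=0.3,
                                               disjoint=True, seed=11)
        truth = {(i, j) for i in range(10) for j in range(i + 1, 10)
                 if abs(prec[i, j]) > 1e-8}
        rng = np.random.default_rng(0)
        covs, ns = [], []
        for _ in range(3):
            x = rng.multivariate_normal(np.zeros(10), np.linalg.inv(prec), size=400)
            z = (x - x.mean(0)) / x.std(0)
            covs.append(z.T @ z / 400)
            ns.append(400)
        best, _ = networks.sweep_and_select(covs, ns)
        pooled = set()
        for sup in best.supports():
            pooled |= {(i, j) for i, j in zip(*np.where(np.triu(sup, 1)))}
        assert edge_f1(pooled, truth) >= 0.8


class TestNetworksAndCentrality:
    def _solution_from_adj(self, adj):
        prec = np.asarray(adj, dtype=float)
        np.fill_diagonal(prec, 2.0)
        return networks.GGLSolution(
            precisions=[prec], sparse_precisions=[prec], covariances=[np.eye(len(adj))],
            n_obs=[50], lambda1=0.1, lambda2=0.01, iterations=1, converged=True)

    def test_path_graph_betweenness(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        sol = self._solution_from_adj(adj)
        _, cent = networks.networks_and_centrality(sol, ["a", "b", "c"])
        assert cent.loc["b", 0] == pytest.approx(1.0)
        assert cent.loc["a", 0] == 0.0 and cent.loc["c", 0] == 0.0

    def test_complete_graph_all_zero(self):
        adj = 1 - np.eye(4)
        sol = self._solution_from_adj(adj)
        _, cent = networks.networks_and_centrality(sol, list("abcd"))
        np.testing.assert_allclose(cent[0].to_numpy(), 0.0)

    def test_matches_brute_force_recount(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            adj = np.triu((r.uniform(size=(8, 8)) < 0.4).astype(int), 1)
            adj = adj + adj.T
            sol = self._solution_from_adj(adj)
            names = [f"n{i}" for i in range(8)]
            _, cent = networks.networks_and_centrality(sol, names)
            expected = betweenness_brute(adj)
            np.testing.assert_allclose(cent[0].loc[names].to_numpy(), expected,
                                       atol=1e-12)


class TestEdgePresenceAndCentralityDifference:
    def _graphs(self, edge_lists):
        graphs = []
        for edges in edge_lists:
            g = nx.Graph()
            g.add_nodes_from("abcd")
            g.add_edges_from(edges)
            graphs.append(g)
        return graphs

    def test_group_specific_edge(self):
        ga = [[("a", "b")], [("a", "b")], [("a", "b")], [], []]
        gb = [[], [], [], [], []]
        graphs = self._graphs(ga + gb)
        out = networks.edge_presence_summary(graphs, ["A"] * 5 + ["B"] * 5)
        assert out.iloc[0].classification == "A-specific"  # 0.6 >= 0.5

    def test_boundary_half_presence_is_shared(self):
        ga = [[("a", "b")], [("a", "b")], [], []]
        gb = [[("a", "b")], [("a", "b")], [], []]
        graphs = self._graphs(ga + gb)
        out = networks.edge_presence_summary(graphs, ["A"] * 4 + ["B"] * 4)
        assert out.iloc[0].classification == "shared"

    def test_manual_classification_tally(self):
        ga = [[("a", "b"), ("b", "c")], [("a", "b")]]
        gb = [[("b", "c"), ("c", "d")], [("b", "c"), ("c", "d")]]
        graphs = self._graphs(ga + gb)
        out = networks.edge_presence_summary(graphs, ["A", "A", "B", "B"])
        cls = dict(zip(zip(out.node1, out.node2), out.classification))
        assert cls[("a", "b")] == "A-specific"
        assert cls[("b", "c")] == "shared"
        assert cls[("c", "d")] == "B-specific"

    def test_centrality_difference_ranks_group_hub_first(self):
        cent = pd.DataFrame({0: [1.0, 0.0], 1: [0.9, 0.1],
                             2: [0.0, 0.0], 3: [0.1, 0.0]},
                            index=["hub", "leaf"])
        out = networks.centrality_difference(cent, ["A", "A", "B", "B"])
        assert out.index[0] == "hub"
        assert out.iloc[0].difference == pytest.approx(0.95 - 0.05)

    def test_identical_groups_zero_difference(self):
        cent = pd.DataFrame({0: [0.5, 0.2], 1: [0.5, 0.2]}, index=["x", "y"])
        out = networks.centrality_difference(cent, ["A", "B"])
        np.testing.assert_allclose(out.difference.to_numpy(), 0.0)
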