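import itertools

import networkx as nx
import numpy as np
import pytest

import mkfbn
from mkfbn.metrics import _cp_lp

from conftest import random_graph


def star(n_leaves=3):
    A = np.zeros((n_leaves + 1, n_leaves + 1), dtype=np.uint8)
    A[0, 1:] = 1
    A[1:, 0] = 1
    return A


def path3():
    A = np.zeros((3, 3), dtype=np.uint8)
    A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
    return A


def triangle():
    return (np.ones((3, 3)) - np.eye(3)).astype(np.uint8)


def two_triangles():
    A = np.zeros((6, 6), dtype=np.uint8)
    A[:3, :3] = triangle()
    A[3:, 3:] = triangle()
    return A


NULLS = mkfbn.NullModelConfig(n_nulls=5, swaps_per_edge=10, seed=0)


class TestNodalMetrics:
    def test_star_by_hand(self):
        nm = mkfbn.nodal_metrics(star(3))
        assert nm.degree[0] == 3
        assert nm.betweenness[0] == pytest.approx(3.0)
        assert nm.efficiency[0] == pytest.approx(1.0)
        np.testing.assert_allclose(nm.efficiency[1:], 2 / 3)
        np.testing.assert_allclose(nm.shortest_path[1:], 5 / 3)

    def test_triangle_clustering(self):
        nm = mkfbn.nodal_metrics(triangle())
        np.testing.assert_allclose(nm.clustering, 1.0)

    def test_degree_sum_is_twice_edge_count(self, rng):
        for _ in range(5):
            A = random_graph(rng, 10)
            nm = mkfbn.nodal_metrics(A)
            assert nm.degree.sum() == A.sum()

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_betweenness_matches_exhaustive_oracle(self, n, rng):
        for _ in range(5):
            A = random_graph(rng, n)
            nm = mkfbn.nodal_metrics(A)
            g = nx.from_numpy_array(A)
            bc = nx.betweenness_centrality(g, normalized=False)
            np.testing.assert_allclose(
                nm.betweenness, [bc[k] for k in range(n)], atol=1e-9
            )

    def test_rejects_invalid_adjacency(self):
        with pytest.raises(ValueError):
            mkfbn.nodal_metrics(np.array([[0, 2], [2, 0]]))
        with pytest.raises(ValueError):
            mkfbn.nodal_metrics(np.array([[0, 1], [0, 0]]))
        with pytest.raises(ValueError):
            mkfbn.nodal_metrics(np.eye(3))


def brute_modularity(A):
    """Best Q over every partition of up to 6 nodes."""
    n = A.shape[0]
    m = A.sum() / 2
    k = A.sum(axis=1)
    best = -1.0
    def q_of(labels):
        q = 0.0
        for c in set(labels):
            idx = [i for i, l in enumerate(labels) if l == c]
            e = A[np.ix_(idx, idx)].sum() / 2 / m
            a = k[idx].sum() / (2 * m)
            q += e - a * a
        return q
    for labels in itertools.product(range(n), repeat=n):
        best = max(best, q_of(labels))
    return best


class TestGlobalMetrics:
    def test_complete_graph_closed_forms(self):
        A = (np.ones((5, 5)) - np.eye(5)).astype(np.uint8)
        gm = mkfbn.global_metrics(A, NULLS)
        assert gm.Eglobal == pytest.approx(1.0)
        assert gm.Cp == pytest.approx(1.0)
        assert gm.Sr == pytest.approx(1.0)  # Laplacian spectrum {0, n, ..., n}
        assert gm.Lp == pytest.approx(1.0)

    def test_path3_closed_forms(self):
        gm = mkfbn.global_metrics(path3(), NULLS)
        assert gm.Lp == pytest.approx(4 / 3)
        assert gm.Sr == pytest.approx(1 / 3)  # eigenvalues {0, 1, 3}

    def test_two_triangles_modularity(self):
        gm = mkfbn.global_metrics(two_triangles(), NULLS)
        assert gm.Q == pytest.approx(0.5)
        assert gm.Q == pytest.approx(brute_modularity(two_triangles()))

    def test_star_assortativity(self):
        gm = mkfbn.global_metrics(star(4), NULLS)
        assert gm.Ar == pytest.approx(-1.0)

    def test_regular_graph_assortativity_flagged(self):
        gm = mkfbn.global_metrics(triangle(), NULLS)
        assert np.isnan(gm.Ar) and "Ar" in gm.flags

    def test_triangle_forced_null_identity(self):
        # a lone triangle admits no double-edge swap: gamma = lambda = 1
        gm = mkfbn.global_metrics(triangle(), NULLS)
        assert gm.gamma == pytest.approx(1.0)
        assert gm.lam == pytest.approx(1.0)
        assert gm.sigma == pytest.approx(1.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            mkfbn.global_metrics(np.zeros((4, 4), dtype=np.uint8), NULLS)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_agrees_with_networkx_oracles(self, n, rng):
        for _ in range(6):
            A = random_graph(rng, n, p=0.5)
            gm = mkfbn.global_metrics(A, NULLS)
            nm = mkfbn.nodal_metrics(A)
            g = nx.from_numpy_array(A)
            np.testing.assert_allclose(
                nm.clustering, [nx.clustering(g, k) for k in range(n)], atol=1e-12
            )
            assert gm.Cp == pytest.approx(np.mean(list(nx.clustering(g).values())))
            assert gm.Eglobal == pytest.approx(nx.global_efficiency(g))
            assert gm.Elocal == pytest.approx(nx.local_efficiency(g))
            ar_nx = nx.degree_assortativity_coefficient(g)
            if np.isnan(gm.Ar) or np.isnan(ar_nx):
                assert np.isnan(gm.Ar) and np.isnan(ar_nx)
            else:
                assert gm.Ar == pytest.approx(ar_nx, abs=1e-9)
            if nx.is_connected(g):
                assert gm.Lp == pytest.approx(nx.average_shortest_path_length(g))
            # synchronization against a direct eigen-decomposition
            L = np.diag(A.sum(axis=1)) - A.astype(float)
            ev = np.linalg.eigvalsh(L)
            assert gm.Sr == pytest.approx(ev[1] / ev[-1])

    def test_isomorphism_invariance(self, rng):
        A = random_graph(rng, 8, p=0.4)
        perm = rng.permutation(8)
        B = A[np.ix_(perm, perm)]
        ga = mkfbn.global_metrics(A, NULLS)
        gb = mkfbn.global_metrics(B, NULLS)
        for name in ("Lp", "Cp", "Eglobal", "Elocal", "Q", "Sr"):
            a, b = getattr(ga, name), getattr(gb, name)
            assert a == pytest.approx(b, abs=1e-9)
        na, nb = mkfbn.nodal_metrics(A), mkfbn.nodal_metrics(B)
        np.testing.assert_allclose(nb.degree, na.degree[perm])
        np.testing.assert_allclose(nb.betweenness, na.betweenness[perm], atol=1e-9)

    def test_eglobal_monotone_along_nested_stack(self, rng):
        series = rng.normal(size=(60, 12))
        grid = mkfbn.SparsityGrid(0.1, 0.5, 0.1)
        stack = mkfbn.threshold_stack(mkfbn.pearson_fbn(series), grid)
        eg = [mkfbn.global_metrics(A, NULLS).Eglobal for A in stack.graphs]
        assert all(b >= a - 1e-12 for a, b in zip(eg[:-1], eg[1:]))


class TestRewireNull:
    def test_degree_sequence_preserved(self, rng):
        A = random_graph(rng, 15, p=0.3)
        for null in mkfbn.rewire_null(A, mkfbn.NullModelConfig(5, 10, 3)):
            np.testing.assert_array_equal(null.sum(axis=1), A.sum(axis=1))
            assert np.all(null == null.T)
            assert not np.diag(null).any()

    def test_deterministic_given_seed(self, rng):
        A = random_graph(rng, 12, p=0.4)
        a = mkfbn.rewire_null(A, mkfbn.NullModelConfig(3, 10, 9))
        b = mkfbn.rewire_null(A, mkfbn.NullModelConfig(3, 10, 9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_er_graph_gamma_lambda_near_one(self):
        # an Erdos-Renyi graph is its own null model up to fluctuations
        gammas, lambdas = [], []
        for seed in range(20):
            g = np.random.default_rng(seed)
            A = random_graph(g, 60, p=0.2)
            cp, lp = _cp_lp(A)
            nulls = mkfbn.rewire_null(A, mkfbn.NullModelConfig(5, 10, seed))
            ncp = np.mean([_cp_lp(x)[0] for x in nulls])
            nlp = np.mean([_cp_lp(x)[1] for x in nulls])
            gammas.append(cp / ncp)
            lambdas.append(lp / nlp)
        assert abs(np.mean(gammas) - 1) < 0.15
        assert abs(np.mean(lambdas) - 1) < 0.15


class TestAucOverThresholds:
    def test_arithmetic_series(self):
        grid = mkfbn.SparsityGrid()  # 49 levels
        vals = np.arange(1.0, 50.0)
        assert mkfbn.auc_over_thresholds(vals, grid, "sum") == pytest.approx(1225.0)
        assert mkfbn.auc_over_thresholds(vals, grid, "step") == pytest.approx(12.25)

    def test_zero_values(self):
        grid = mkfbn.SparsityGrid(0.1, 0.5, 0.1)
        assert mkfbn.auc_over_thresholds(np.zeros(5), grid) == 0.0

    def test_rejects_bad_input(self):
        grid = mkfbn.SparsityGrid(0.1, 0.5, 0.1)
        with pytest.raises(ValueError, match="one per grid point"):
            mkfbn.auc_over_thresholds(np.zeros(4), grid)
        vals = np.zeros(5)
        vals[2] = np.nan
        with pytest.raises(ValueError, match=r"missing values.*\[2\]"):
            mkfbn.auc_over_thresholds(vals, grid)
        with pytest.raises(ValueError, match="unknown AUC mode"):
            mkfbn.auc_over_thresholds(np.zeros(5), grid, "trapezoid")

    def test_constant_metric_sums_to_grid_length(self, rng):
        grid = mkfbn.SparsityGrid()
        assert mkfbn.auc_over_thresholds(np.ones(49), grid, "sum") == 49.0
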