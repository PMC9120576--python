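import numpy as np
import pytest
from scipy import optimize
from sklearn.svm import SVC

import mkfbn
from mkfbn.mksvm import dual_objective


def qp_oracle(K, y, C):
    """Generic constrained-QP solution of the SVM dual (SLSQP)."""
    n = len(y)
    Q = np.outer(y, y) * K

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def neg_grad(a):
        return -(np.ones(n) - Q @ a)

    res = optimize.minimize(
        neg_obj, np.zeros(n), jac=neg_grad, method="trust-constr",
        bounds=optimize.Bounds(np.zeros(n), np.full(n, C)),
        constraints=optimize.LinearConstraint(y[None, :], 0.0, 0.0),
        options={"maxiter": 5000, "gtol": 1e-12, "xtol": 1e-14},
    )
    return res.x


class TestBuildKernel:
    def test_single_feature_example(self):
        kb = mkfbn.build_kernel(np.array([[1.0], [-1.0]]))
        np.testing.assert_allclose(kb.gram, [[1, -1], [-1, 1]], atol=1e-12)
        assert kb.normalizer == pytest.approx(1.0)

    def test_duplicated_subjects_have_identical_rows(self, rng):
        X = rng.normal(size=(5, 7))
        X[3] = X[1]
        kb = mkfbn.build_kernel(X)
        np.testing.assert_allclose(kb.gram[1], kb.gram[3], atol=1e-12)

    def test_gram_is_psd(self, rng):
        for _ in range(100):
            X = rng.normal(size=(rng.integers(3, 12), rng.integers(2, 20)))
            kb = mkfbn.build_kernel(X)
            assert np.linalg.eigvalsh(kb.gram).min() >= -1e-8

    def test_zero_variance_features_dropped(self, rng):
        X = rng.normal(size=(6, 4))
        X[:, 2] = 3.0
        kb = mkfbn.build_kernel(X)
        assert kb.kept.sum() == 3

    def test_test_rows_use_training_statistics(self, rng):
        X = rng.normal(size=(8, 5))
        T = rng.normal(size=(2, 5))
        kb = mkfbn.build_kernel(X, T)
        mu, sd = X.mean(0), X.std(0)
        Z = (X - mu) / sd
        Zt = (T - mu) / sd
        np.testing.assert_allclose(kb.test_rows, Zt @ Z.T / kb.normalizer,
                                   atol=1e-12)


class TestCombineKernels:
    def test_vertex_recovers_block(self, rng):
        A = rng.normal(size=(4, 4))
        B = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(
            mkfbn.combine_kernels([A, B], [1.0, 0.0]), A
        )

    def test_convexity_fixed_point(self, rng):
        A = rng.normal(size=(4, 4))
        np.testing.assert_allclose(
            mkfbn.combine_kernels([A, A.copy()], [0.3, 0.7]), A, atol=1e-12
        )

    def test_combination_of_psd_is_psd(self, rng):
        for _ in range(20):
            X1 = rng.normal(size=(6, 4))
            X2 = rng.normal(size=(6, 9))
            K = mkfbn.combine_kernels([X1 @ X1.T, X2 @ X2.T], [0.5, 0.5])
            assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_invalid_inputs(self, rng):
        A = rng.normal(size=(3, 3))
        with pytest.raises(ValueError):
            mkfbn.combine_kernels([A], [0.5, 0.5])
        with pytest.raises(ValueError):
            mkfbn.combine_kernels([A, A], [0.9, 0.9])
        with pytest.raises(ValueError):
            mkfbn.combine_kernels([A, rng.normal(size=(4, 4))], [0.5, 0.5])


class TestFit:
    def test_two_point_worked_example(self):
        K = np.array([[1.0, -1.0], [-1.0, 1.0]])
        y = np.array([1.0, -1.0])
        model = mkfbn.fit(K, y, C=10.0)
        np.testing.assert_allclose(model.alpha, [0.5, 0.5], atol=1e-8)
        assert model.b == pytest.approx(0.0, abs=1e-8)
        a_qp = qp_oracle(K, y, 10.0)
        np.testing.assert_allclose(model.alpha, a_qp, atol=1e-6)
        # decision at x = 0.2 against the closed form f(x) = x
        f = mkfbn.decision_values(model, np.array([[0.2, -0.2]]))
        assert f[0] == pytest.approx(0.2, abs=1e-8)

    def test_kkt_and_objective_against_qp_oracle(self, rng):
        for trial in range(10):
            n = int(rng.integers(6, 20))
            X = rng.normal(size=(n, 5))
            y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            if abs(y.sum()) == n:
                y[0] = -y[0]
            K = X @ X.T / 5
            for C in (0.5, 8.0):
                model = mkfbn.fit(K, y, C)
                assert mkfbn.kkt_residual(model, K) <= 1e-6
                assert abs((model.alpha * y).sum()) <= 1e-8
                a_qp = qp_oracle(K, y, C)
                obj_qp = a_qp.sum() - 0.5 * (a_qp * y) @ K @ (a_qp * y)
                assert dual_objective(model, K) == pytest.approx(obj_qp, abs=1e-6)

    def test_matches_libsvm_decision_values(self, rng):
        X = rng.normal(size=(15, 6))
        y = np.array([1.0] * 8 + [-1.0] * 7)
        K = X @ X.T / 6
        model = mkfbn.fit(K, y, 2.0)
        svc = SVC(kernel="precomputed", C=2.0, tol=1e-10).fit(K, y)
        np.testing.assert_allclose(
            mkfbn.decision_values(model, K), svc.decision_function(K), atol=1e-6
        )

    def test_label_flip_negates_decisions(self, rng):
        X = rng.normal(size=(12, 4))
        y = np.array([1.0] * 6 + [-1.0] * 6)
        K = X @ X.T
        m1 = mkfbn.fit(K, y, 1.0)
        m2 = mkfbn.fit(K, -y, 1.0)
        np.testing.assert_allclose(
            mkfbn.decision_values(m1, K), -mkfbn.decision_values(m2, K), atol=1e-5
        )
        assert m1.b == pytest.approx(-m2.b, abs=1e-5)

    def test_separable_data_fits_perfectly(self, rng):
        X = np.vstack([rng.normal(size=(10, 3)) + 6, rng.normal(size=(10, 3)) - 6])
        y = np.array([1.0] * 10 + [-1.0] * 10)
        K = X @ X.T
        model = mkfbn.fit(K, y, 100.0)
        pred = np.where(mkfbn.decision_values(model, K) > 0, 1, -1)
        assert (pred == y).all()

    def test_input_validation(self):
        K = np.eye(3)
        with pytest.raises(ValueError):
            mkfbn.fit(K, np.array([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            mkfbn.fit(K, np.array([1.0, -1.0, 0.5]), 1.0)
        with pytest.raises(ValueError):
            mkfbn.fit(K, np.array([1.0, -1.0, 1.0]), -1.0)


class TestDecide:
    def test_support_vector_reproduces_training_decision(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.array([1.0] * 5 + [-1.0] * 5)
        kb = mkfbn.build_kernel(X, X)
        model = mkfbn.fit(kb.gram, y, 1.0, beta=np.array([1.0]))
        f_train = mkfbn.decision_values(model, kb.gram)
        f_test, labels = mkfbn.decide(model, [kb.test_rows])
        np.testing.assert_allclose(f_test, f_train, atol=1e-8)

    def test_zero_decision_goes_negative(self):
        model = mkfbn.SVMModel(np.zeros(2), 0.0, 1.0, np.array([1.0, -1.0]),
                               np.array([1.0]))
        f, labels = mkfbn.decide(model, [np.zeros((1, 2))])
        assert f[0] == 0.0 and labels[0] == -1

    def test_vertex_beta_equals_single_kernel(self, rng):
        # the multi-kernel model at a simplex vertex is the single-kernel SVM
        X1 = rng.normal(size=(14, 10))
        X2 = rng.normal(size=(14, 3))
        y = np.array([1.0] * 7 + [-1.0] * 7)
        k1 = mkfbn.build_kernel(X1, X1[:3])
        k2 = mkfbn.build_kernel(X2, X2[:3])
        beta = np.array([1.0, 0.0])
        mk = mkfbn.fit(mkfbn.combine_kernels([k1.gram, k2.gram], beta), y, 2.0,
                       beta=beta)
        single = mkfbn.fit(k1.gram, y, 2.0)
        f_mk, _ = mkfbn.decide(mk, [k1.test_rows, k2.test_rows])
        f_single = mkfbn.decision_values(single, k1.test_rows)
        np.testing.assert_allclose(f_mk, f_single, atol=1e-8)


class TestTune:
    def test_simplex_grid_counts(self):
        assert len(mkfbn.simplex_grid(3, 0.1)) == 66  # C(12, 2)
        assert len(mkfbn.simplex_grid(2, 0.1)) == 11
        np.testing.assert_array_equal(mkfbn.simplex_grid(1, 0.1), [[1.0]])
        grid = mkfbn.simplex_grid(3, 0.2)
        np.testing.assert_allclose(grid.sum(axis=1), 1.0)

    def test_default_c_grid(self):
        hyper = mkfbn.HyperGrid()
        assert len(hyper.c_values) == 11
        assert hyper.c_values[0] == 2.0 ** -5
        assert hyper.c_values[-1] == 2.0 ** 5

    def test_single_block_reduces_to_c_search(self, rng):
        X = np.vstack([rng.normal(size=(8, 3)) + 2, rng.normal(size=(8, 3)) - 2])
        y = np.array([1.0] * 8 + [-1.0] * 8)
        kb = mkfbn.build_kernel(X)
        C, beta, score = mkfbn.tune([kb.gram], y, mkfbn.HyperGrid(), seed=0)
        np.testing.assert_array_equal(beta, [1.0])
        assert score > 0.9  # separable clusters rank near-perfectly

    def test_degenerate_inner_split_rejected(self, rng):
        kb = mkfbn.build_kernel(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            mkfbn.tune([kb.gram], np.array([1.0, 1.0, -1.0]), mkfbn.HyperGrid())

    def test_deterministic(self, rng):
        X1 = rng.normal(size=(12, 6))
        X2 = rng.normal(size=(12, 4))
        y = np.array([1.0] * 6 + [-1.0] * 6)
        grams = [mkfbn.build_kernel(X1).gram, mkfbn.build_kernel(X2).gram]
        out1 = mkfbn.tune(grams, y, mkfbn.HyperGrid(beta_step=0.5), seed=3)
        out2 = mkfbn.tune(grams, y, mkfbn.HyperGrid(beta_step=0.5), seed=3)
        assert out1[0] == out2[0]
        np.testing.assert_array_equal(out1[1], out2[1])
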