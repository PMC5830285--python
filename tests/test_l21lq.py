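import numpy as np
import pytest

from sparsemtl import (MultitaskDataset, build_pool, factor_kernels, fit_l21lq,
                       objective_and_gradient, predict_l21lq, project_Q,
                       solve_alpha_q)
from sparsemtl.kernels import KernelPool, KernelSpec, gram_matrix
from sparsemtl.l21lq import L21LqModel, _feature_qbar

from oracles import krr_predict


def _pool_from_gram(G, X=None):
    """Wrap a precomputed unit-trace Gram in a pool (linear spec is a stand-in)."""
    m = G.shape[0]
    return KernelPool(specs=[KernelSpec("linear")], gram_train=[G],
                      traces=[1.0], X_train=X if X is not None else np.eye(m),
                      columns=[np.arange(G.shape[0] if X is None else X.shape[1])],
                      block=[None])


class TestFeatureExponent:
    def test_values(self):
        assert _feature_qbar(1.0) == 1.0
        assert _feature_qbar(1.5) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            _feature_qbar(2.0)


class TestFactorKernels:
    def test_identity_gram_gives_selector_maps(self):
        G = np.eye(5)
        rows = [np.array([0, 1, 2]), np.array([2, 3, 4])]
        fac = factor_kernels(_pool_from_gram(G), rows)[0]
        assert fac.rank == 5
        for t, r in enumerate(rows):
            np.testing.assert_allclose(fac.maps[t].T @ fac.maps[t],
                                       G[np.ix_(r, r)], atol=1e-10)

    def test_rank_one_gram(self, rng):
        v = rng.normal(size=6)
        G = np.outer(v, v)
        fac = factor_kernels(_pool_from_gram(G), [np.arange(6)])[0]
        assert fac.rank == 1
        np.testing.assert_allclose(fac.maps[0].T @ fac.maps[0], G, atol=1e-10)

    def test_reconstruction_identity_random_psd(self, rng):
        A = rng.normal(size=(8, 8))
        G = A @ A.T
        rows = [np.array([0, 2, 4]), np.array([1, 3, 5, 7])]
        fac = factor_kernels(_pool_from_gram(G), rows)[0]
        for t, rt in enumerate(rows):
            for u, ru in enumerate(rows):
                np.testing.assert_allclose(fac.maps[t].T @ fac.maps[u],
                                           G[np.ix_(rt, ru)], atol=1e-8)

    def test_non_psd_rejected(self):
        G = np.diag([1.0, -0.5])
        with pytest.raises(ValueError, match="PSD"):
            factor_kernels(_pool_from_gram(G), [np.arange(2)])


class TestSolveAlphaQ:
    def test_scaled_identity_reduces_to_krr(self, rng):
        X = rng.standard_normal((20, 3))
        G = gram_matrix(KernelSpec("gaussian", 1.0), X, X)
        y = rng.standard_normal(20)
        fac = factor_kernels(_pool_from_gram(G, X), [np.arange(20)])
        c, lam = 0.7, 3.0
        alpha = solve_alpha_q(fac, [c * np.eye(fac[0].rank)], lam, [y])
        expected = -np.linalg.solve(c * G + np.eye(20) / lam, y)
        np.testing.assert_allclose(alpha[0], expected, atol=1e-8)

    def test_zero_y(self, rng):
        X = rng.standard_normal((10, 2))
        G = gram_matrix(KernelSpec("linear"), X, X)
        fac = factor_kernels(_pool_from_gram(G, X), [np.arange(10)])
        alpha = solve_alpha_q(fac, [np.eye(fac[0].rank)], 2.0, [np.zeros(10)])
        np.testing.assert_array_equal(alpha[0], 0.0)

    def test_zero_q_gives_minus_lam_y(self, rng):
        X = rng.standard_normal((10, 2))
        G = gram_matrix(KernelSpec("gaussian", 1.0), X, X)
        y = rng.standard_normal(10)
        fac = factor_kernels(_pool_from_gram(G, X), [np.arange(10)])
        alpha = solve_alpha_q(fac, [np.zeros((fac[0].rank,) * 2)], 2.5, [y])
        np.testing.assert_allclose(alpha[0], -2.5 * y, atol=1e-10)


class TestObjectiveGradient:
    def test_q_zero_value(self, rng):
        X = rng.standard_normal((12, 3))
        G = gram_matrix(KernelSpec("gaussian", 1.0), X, X)
        y = [rng.standard_normal(12), rng.standard_normal(12)]
        fac = factor_kernels(_pool_from_gram(G, X), [np.arange(12)] * 2)
        lam = 1.7
        f, grads, alpha = objective_and_gradient(fac, [np.zeros((12, 12))], lam, y)
        expected = sum(lam / 2 * yt @ yt for yt in y)
        assert f == pytest.approx(expected, rel=1e-10)

    def test_gradient_blocks_negative_psd(self, rng):
        X = rng.standard_normal((15, 3))
        pool = build_pool(X, bandwidths=(1.0,), degrees=(1,))
        y = [rng.standard_normal(15)]
        fac = factor_kernels(pool, [np.arange(15)])
        Q = [np.eye(f.rank) / (2.0 * f.rank) for f in fac]
        _, grads, _ = objective_and_gradient(fac, Q, 2.0, y)
        for g in grads:
            assert np.linalg.eigvalsh(-2.0 * g)[0] >= -1e-10

    def test_finite_difference_through_resolved_alpha(self, rng):
        X = rng.standard_normal((10, 2))
        pool = build_pool(X, bandwidths=(1.0,), degrees=(2,))
        y = [rng.standard_normal(10)]
        fac = factor_kernels(pool, [np.arange(10)])
        Q = [0.01 * np.eye(f.rank) for f in fac]
        lam = 2.0
        f0, grads, _ = objective_and_gradient(fac, Q, lam, y)
        eps = 1e-6
        for j in range(2):
            for idx in [(0, 0), (1, 1), (0, 1)]:
                E = np.zeros_like(Q[j])
                E[idx] = eps
                E[idx[::-1]] = eps
                Qp = [q.copy() for q in Q]
                Qm = [q.copy() for q in Q]
                Qp[j] = Q[j] + E
                Qm[j] = Q[j] - E
                fp, _, _ = objective_and_gradient(fac, Qp, lam, y)
                fm, _, _ = objective_and_gradient(fac, Qm, lam, y)
                num = (fp - fm) / (2 * eps)
                sym = 2.0 if idx[0] != idx[1] else 1.0
                assert grads[j][idx] * sym == pytest.approx(num, abs=1e-4)


class TestProjectQ:
    def test_feasible_unchanged(self):
        Q = [0.2 * np.eye(2), 0.1 * np.eye(3)]    # trace sum 0.7 <= 1
        out = project_Q(Q, qbar=1.0)
        for a, b in zip(out, Q):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_trace_rescale_arithmetic(self):
        out = project_Q([2.0 * np.eye(2)], qbar=1.0)
        np.testing.assert_allclose(out[0], 0.5 * np.eye(2), atol=1e-12)

    def test_negative_eigenvalue_clipped(self):
        Q = [np.diag([1.0, -0.4])]
        out = project_Q(Q, qbar=2.0)
        w = np.linalg.eigvalsh(out[0])
        assert w[0] >= -1e-12
        assert np.trace(out[0]) <= 1.0 + 1e-12

    def test_total_projection_always_feasible(self, rng):
        for _ in range(5):
            Q = [rng.normal(size=(3, 3)) for _ in range(2)]
            Q = [0.5 * (q + q.T) for q in Q]
            out = project_Q(Q, qbar=3.0)
            total = sum(max(np.trace(q), 0) ** 3.0 for q in out)
            assert total <= 1.0 + 1e-9
            for q in out:
                assert np.linalg.eigvalsh(q)[0] >= -1e-9


class TestFit:
    def test_best_iterate_no_worse_than_init(self, rng):
        X = rng.standard_normal((25, 4))
        Y = rng.standard_normal((25, 2))
        ds = MultitaskDataset(X=X, Y=Y)
        pool = build_pool(X, bandwidths=(1.0,), degrees=(1,))
        model = fit_l21lq(ds, pool, q=1.5, lam=3.0, max_outer=25)
        assert model.best_objective <= model.objective_trace[0] + 1e-12

    def test_source_kernel_gets_larger_trace(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(2000 + seed)
            X = r.standard_normal((50, 3))
            K_src = gram_matrix(KernelSpec("gaussian", 1.0), X, X)
            c = np.zeros((50, 2))
            c[r.choice(50, 6, replace=False)] = r.standard_normal((6, 2))
            F = K_src @ c
            F /= F.std(0)
            Y = F + 0.1 * r.standard_normal((50, 2))
            ds = MultitaskDataset(X=X, Y=Y)
            pool = build_pool(X, bandwidths=(1.0,), degrees=(),
                              include_linear=True)
            model = fit_l21lq(ds, pool, q=1.5, lam=50.0, max_outer=40)
            traces = [np.trace(Qj) for Qj in model.Q]
            hits += int(traces[0] > traces[1])
        assert hits >= 0.8 * n_seeds

    def test_q_out_of_range(self, rng, small_dataset):
        pool = build_pool(small_dataset.X, bandwidths=(1.0,), degrees=())
        with pytest.raises(ValueError):
            fit_l21lq(small_dataset, pool, q=2.0, lam=1.0)


class TestPredict:
    def test_identity_q_training_rows_match_krr(self, rng):
        X = rng.standard_normal((25, 3))
        y = rng.standard_normal(25)
        ds = MultitaskDataset(X=X, Y=y[:, None])
        pool = build_pool(X, bandwidths=(1.0,), degrees=(), include_linear=False)
        lam = 4.0
        rows = [np.arange(25)]
        fac = factor_kernels(pool, rows, rank_tol=1e-13)
        Q = [np.eye(fac[0].rank)]
        alpha = solve_alpha_q(fac, Q, lam, [y])
        model = L21LqModel(Q=Q, alpha=alpha, lam=lam, q=1.5, qbar=3.0,
                           factors=fac, task_rows=rows, pool=pool)
        pred = predict_l21lq(model, X)
        K = pool.gram_train[0]
        np.testing.assert_allclose(pred[:, 0], krr_predict(K, K, y, lam),
                                   atol=1e-8)

    def test_zero_alpha(self, rng):
        X = rng.standard_normal((15, 3))
        ds = MultitaskDataset(X=X, Y=rng.standard_normal((15, 1)))
        pool = build_pool(X, bandwidths=(1.0,), degrees=())
        model = fit_l21lq(ds, pool, q=1.5, lam=1.0, max_outer=3)
        model.alpha = [np.zeros_like(model.alpha[0])]
        assert np.all(predict_l21lq(model, X) == 0)

    def test_eigenvector_sign_invariance(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        ds = MultitaskDataset(X=X, Y=y[:, None])
        pool = build_pool(X, bandwidths=(1.5,), degrees=(), include_linear=False)
        model = fit_l21lq(ds, pool, q=1.5, lam=3.0, max_outer=10)
        pred = predict_l21lq(model, X[:6])
        # flip the sign of every eigenvector; maps and Q transform together
        fac = model.factors[0]
        S = np.diag(np.where(np.arange(fac.rank) % 2 == 0, -1.0, 1.0))
        fac.eigvecs = fac.eigvecs @ S
        fac.maps = [S @ M for M in fac.maps]
        model.Q = [S @ model.Q[0] @ S]
        np.testing.assert_allclose(predict_l21lq(model, X[:6]), pred, atol=1e-10)


class TestKernelizationIdentity:
    def test_gram_route_equals_explicit_features(self, rng):
        """With an explicit finite-dimensional map, the Gram-side objective
        must equal the feature-side objective for matched Q."""
        m, p = 12, 2
        X = rng.standard_normal((m, p))
        # explicit degree-2 polynomial feature map for (x.z + 1)^2
        def phi(x):
            x1, x2 = x
            return np.array([1.0, np.sqrt(2) * x1, np.sqrt(2) * x2,
                             x1 ** 2, np.sqrt(2) * x1 * x2, x2 ** 2])
        F = np.vstack([phi(x) for x in X])          # m x 6
        G_raw = F @ F.T
        np.testing.assert_allclose(G_raw, (X @ X.T + 1.0) ** 2, atol=1e-10)
        tr = np.trace(G_raw)
        G = G_raw / tr
        Fs = F / np.sqrt(tr)                        # so Fs Fs^T = G
        y = [rng.standard_normal(m)]
        lam = 2.0
        fac = factor_kernels(_pool_from_gram(G, X), [np.arange(m)])[0]
        r = fac.rank
        rng2 = np.random.default_rng(7)
        A = rng2.normal(size=(r, r))
        Q = A @ A.T
        Q = Q / (2 * np.trace(Q))                   # strictly feasible
        f_gram, _, _ = objective_and_gradient([fac], [Q], lam, y)
        # feature route: Qbar = U Q U^T with U = Fs^T V S^{-1}
        U = Fs.T @ fac.eigvecs / np.sqrt(fac.eigvals)
        Qbar = U @ Q @ U.T
        A_feat = Fs @ Qbar @ Fs.T + np.eye(m) / lam
        alpha = -np.linalg.solve(A_feat, y[0])
        quad = alpha @ (Fs @ Qbar @ Fs.T) @ alpha
        f_feat = -alpha @ y[0] - 0.5 * quad - (alpha @ alpha) / (2 * lam)
        assert f_gram == pytest.approx(f_feat, abs=1e-8)
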