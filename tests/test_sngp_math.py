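"""Mathematical oracles for the SNGP building blocks: power-iteration
spectral norms vs exact SVD, random-Fourier-feature kernel approximation vs
the closed-form RBF kernel, the convex MAP head fit vs an independent
ridge-logistic solver, and GP predictive-variance contracts."""

import numpy as np
import pytest

from trustwsi.sngp import (
    RFFHead,
    fit_head,
    power_iteration,
    predict,
    rff_features,
    spectral_normalize,
)


class TestSpectralNormalize:
    def test_diagonal_matrix(self):
        W = np.diag([2.0, 0.5])
        Wn, lam = spectral_normalize(W, c=1.0)
        assert lam == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(Wn, np.diag([1.0, 0.25]), atol=1e-9)

    def test_untouched_when_norm_below_bound(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((5, 5))
        W *= 0.5 / np.linalg.svd(W, compute_uv=False)[0]
        Wn, lam = spectral_normalize(W, c=1.0)
        assert Wn is W  # exactly unchanged, not a scaled copy
        assert lam == pytest.approx(0.5, abs=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_power_iteration_matches_svd(self, seed):
        # convergence rate is (sigma2/sigma1)^(2*n_iter): 50 iterations reach
        # 1e-6 whenever the spectral gap is not near-degenerate; matrices with
        # sigma2/sigma1 > 0.9 get extra iterations instead
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((8, 8))
        s = np.linalg.svd(W, compute_uv=False)
        n_iter = 50 if s[1] / s[0] <= 0.9 else 500
        lam, _ = power_iteration(W, n_iter=n_iter)
        assert abs(lam - s[0]) < 1e-6

    def test_zero_matrix_warns_and_returns_unchanged(self):
        W = np.zeros((3, 3))
        with pytest.warns(UserWarning):
            Wn, lam = spectral_normalize(W, c=1.0)
        assert lam == 0.0
        np.testing.assert_array_equal(Wn, W)

    def test_rectangular(self):
        rng = np.random.default_rng(7)
        W = rng.standard_normal((6, 3))
        lam, _ = power_iteration(W, n_iter=100)
        assert lam == pytest.approx(np.linalg.svd(W, compute_uv=False)[0], abs=1e-8)

    def test_nonpositive_bound_rejected(self):
        with pytest.raises(ValueError):
            spectral_normalize(np.eye(2), c=0.0)


class TestRFFKernel:
    def test_self_inner_product_is_one(self):
        # k(x, x) = 1 for the RBF kernel; Monte-Carlo over random heads
        rng = np.random.default_rng(1)
        D = 1024
        vals = []
        for seed in range(5):
            head = RFFHead(feature_dim=6, D_L=D, rng=np.random.default_rng(seed))
            h = rng.standard_normal((1, 6))
            Phi = rff_features(h, head)
            vals.append((Phi @ Phi.T).item())
        assert abs(np.mean(vals) - 1.0) < 3.0 / np.sqrt(D)

    def test_cross_product_approximates_rbf(self):
        rng = np.random.default_rng(2)
        head = RFFHead(feature_dim=4, D_L=4096, rng=rng)
        H = rng.standard_normal((20, 4))
        Phi = rff_features(H, head)
        G = Phi @ Phi.T
        d2 = ((H[:, None] - H[None]) ** 2).sum(-1)
        K = np.exp(-d2 / 2.0)
        assert np.max(np.abs(G - K)) < 0.05

    def test_gram_error_shrinks_with_feature_dimension(self):
        # entrywise error of ΦΦᵀ vs the RBF kernel decays like 1/sqrt(D_L)
        rng = np.random.default_rng(3)
        H = rng.standard_normal((30, 5))
        d2 = ((H[:, None] - H[None]) ** 2).sum(-1)
        K = np.exp(-d2 / 2.0)
        errs = {}
        for D in (256, 1024, 4096):
            e = []
            for rep in range(3):
                head = RFFHead(feature_dim=5, D_L=D, rng=np.random.default_rng(100 * D + rep))
                Phi = rff_features(H, head)
                e.append(np.mean(np.abs(Phi @ Phi.T - K)))
            errs[D] = np.mean(e)
        assert errs[1024] < errs[256]
        assert errs[4096] < errs[1024]
        # rate check: quadrupling D should roughly halve the error
        assert errs[4096] < 0.75 * errs[1024]

    def test_norm_invariant_under_coordinate_permutation(self):
        rng = np.random.default_rng(4)
        head = RFFHead(feature_dim=3, D_L=64, rng=rng)
        h = rng.standard_normal((2, 3))
        Phi = rff_features(h, head)
        perm = rng.permutation(64)
        assert np.linalg.norm(Phi[:, perm]) == pytest.approx(np.linalg.norm(Phi))

    def test_dimension_mismatch_raises(self):
        head = RFFHead(feature_dim=3, D_L=16)
        with pytest.raises(ValueError):
            rff_features(np.zeros((2, 5)), head)

    def test_projection_is_immutable(self):
        head = RFFHead(feature_dim=3, D_L=16)
        with pytest.raises(ValueError):
            head.W_L[0, 0] = 1.0


class TestFitHead:
    def test_separable_features_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(5)
        Phi = np.vstack([rng.normal(-2, 0.3, (40, 8)), rng.normal(2, 0.3, (40, 8))])
        y = np.repeat([0, 1], 40)
        head = fit_head(Phi, y, tau=1.0)
        mu = Phi @ head.beta
        assert (mu.argmax(axis=1) == y).mean() == 1.0

    def test_empty_training_gives_prior_precision(self):
        head = RFFHead(feature_dim=4, D_L=16, tau=2.5)
        fit_head(np.zeros((0, 16)), np.zeros(0, dtype=int), tau=2.5, head=head)
        np.testing.assert_allclose(head.precision, 2.5 * np.eye(16))

    def test_single_class_labels_rejected(self):
        from trustwsi.sngp import DegenerateFitError

        with pytest.raises(DegenerateFitError):
            fit_head(np.random.default_rng(0).standard_normal((10, 4)), np.zeros(10, dtype=int))

    def test_map_matches_ridge_logistic_oracle(self):
        # independent oracle: sklearn ridge-regularized logistic regression.
        # our symmetric two-column MAP (prior N(0, I) on both columns) equals
        # the single-vector parametrization w = beta_1 - beta_0 with penalty
        # ||w||^2/4, i.e. sklearn's C=2.
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(6)
        Phi = rng.standard_normal((50, 16))
        w_true = rng.standard_normal(16)
        y = (Phi @ w_true + 0.3 * rng.standard_normal(50) > 0).astype(int)
        head = fit_head(Phi, y, tau=1.0, max_iter=2000)
        w_mine = head.beta[:, 1] - head.beta[:, 0]
        oracle = LogisticRegression(C=2.0, fit_intercept=False, max_iter=5000, tol=1e-10)
        oracle.fit(Phi, y)
        np.testing.assert_allclose(w_mine, oracle.coef_.ravel(), atol=1e-3)
        # symmetry of the two-column MAP
        np.testing.assert_allclose(head.beta[:, 0], -head.beta[:, 1], atol=1e-5)


class TestPredict:
    def _bare_head(self, D=32, tau=1.0):
        head = RFFHead(feature_dim=8, D_L=D, tau=tau, rng=np.random.default_rng(0))
        return head

    def test_prior_uncertainty_is_one(self):
        # with no training data, uncertainty = phi' phi which is ~1 for RFF
        head = self._bare_head(D=512)
        fit_head(np.zeros((0, 512)), np.zeros(0, dtype=int), head=head)
        Phi = head.features(np.random.default_rng(1).standard_normal((20, 8)))
        out = predict(head, Phi, n_mc_softmax=0)
        np.testing.assert_allclose(out.uncertainty, 1.0, atol=0.2)

    def test_training_data_at_query_point_reduces_uncertainty(self):
        head = self._bare_head(D=64)
        rng = np.random.default_rng(2)
        h_star = rng.standard_normal((1, 8))
        Phi_star = head.features(h_star)
        prior = head.tau * (Phi_star @ np.linalg.solve(head.precision, Phi_star.T)).item()
        Phi_train = np.repeat(Phi_star, 100, axis=0)
        precision = Phi_train.T @ Phi_train + head.tau * np.eye(64)
        post = head.tau * (Phi_star @ np.linalg.solve(precision, Phi_star.T)).item()
        assert post < prior
        # rank-one-update oracle: each added copy can only shrink the variance
        prev = prior
        P = head.tau * np.eye(64)
        for _ in range(5):
            P = P + Phi_star.T @ Phi_star
            cur = head.tau * (Phi_star @ np.linalg.solve(P, Phi_star.T)).item()
            assert cur < prev + 1e-12
            prev = cur

    def test_zero_variance_limit_recovers_plain_softmax(self):
        head = self._bare_head(D=16)
        rng = np.random.default_rng(3)
        Phi = head.features(rng.standard_normal((5, 8)))
        beta = rng.standard_normal((16, 2))
        # huge precision => variance ~ 0
        head.set_posterior(beta, 1e12 * np.eye(16))
        out = predict(head, Phi, n_mc_softmax=200, rng=np.random.default_rng(0))
        mu = Phi @ beta
        expected = np.exp(mu) / np.exp(mu).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out.probs, expected, atol=1e-5)
        np.testing.assert_allclose(out.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_mean_field_close_to_monte_carlo(self):
        head = self._bare_head(D=64)
        rng = np.random.default_rng(4)
        Phi_train = head.features(rng.standard_normal((200, 8)))
        y = rng.integers(0, 2, 200)
        fit_head(Phi_train, y, head=head)
        Phi = head.features(rng.standard_normal((10, 8)))
        mf = predict(head, Phi, n_mc_softmax=0).probs
        mc = predict(head, Phi, n_mc_softmax=20000, rng=np.random.default_rng(1)).probs
        np.testing.assert_allclose(mf, mc, atol=0.03)

    def test_variance_grows_with_distance_from_training_cloud(self):
        # monotone along a ray on 2-D latents
        head = RFFHead(feature_dim=2, D_L=256, rng=np.random.default_rng(5))
        rng = np.random.default_rng(6)
        H = rng.standard_normal((500, 2)) * 0.5
        y = (H[:, 0] > 0).astype(int)
        fit_head(head.features(H), y, head=head)
        ray = np.array([[t, 0.0] for t in (0.0, 2.0, 4.0, 8.0, 16.0)])
        out = predict(head, head.features(ray), n_mc_softmax=0)
        # exact-GP variance is monotone along the ray; the finite-D RFF
        # approximation wiggles by O(1/sqrt(D_L)) once it saturates near 1
        assert np.all(np.diff(out.uncertainty) > -0.05)
        assert out.uncertainty[1] > out.uncertainty[0]
        assert out.uncertainty[-1] > 0.8
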