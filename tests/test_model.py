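"""Unit and property tests for the clustering solver."""

import math

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.cluster import KMeans

from oracles import (grid_min_membership, grid_min_saliency,
                     naive_background_moments, naive_class_moments,
                     naive_saliency_prior, random_instance)
from saliencyfcm.config import AlgorithmConfig
from saliencyfcm.model import (ClusterParameters, MembershipState,
                               PixelFeatureMatrix, dissimilarity,
                               extract_features, fcm_initialize,
                               fuzzy_c_means, gaussian_log_pdf, objective,
                               run_segmentation, saliency_kl,
                               update_background_params, update_class_params,
                               update_membership, update_saliency,
                               update_saliency_prior)


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

class TestGaussianLogPdf:
    def test_normalising_constant_cancels_exponent(self):
        assert gaussian_log_pdf(0.0, 0.0, 1.0 / (2 * np.pi)) == pytest.approx(0.0)

    @pytest.mark.parametrize("var", [0.3, 1.0, 58.0 ** 2])
    def test_at_mean_only_constant_remains(self, var):
        assert gaussian_log_pdf(5.0, 5.0, var) == pytest.approx(
            -0.5 * math.log(2 * math.pi * var))

    @pytest.mark.parametrize("x,mean,var", [
        (2.0, 0.0, 4.0), (128.0, 60.0, 100.0), (-3.0, 1.5, 0.25)])
    def test_matches_scipy(self, x, mean, var):
        assert gaussian_log_pdf(x, mean, var) == pytest.approx(
            norm.logpdf(x, loc=mean, scale=math.sqrt(var)), rel=1e-12)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            gaussian_log_pdf(np.nan, 0.0, 1.0)
        with pytest.raises(ValueError):
            gaussian_log_pdf(0.0, 0.0, -1.0)


# ---------------------------------------------------------------------------
# FCM initialisation
# ---------------------------------------------------------------------------

class TestFCM:
    def test_two_blobs_recover_centres(self, rng):
        x = np.concatenate([rng.normal(60, 5, 500), rng.normal(180, 5, 500)])
        X = x[:, None]
        centers, u = fuzzy_c_means(X, 2, rng=np.random.default_rng(0))
        got = np.sort(centers.ravel())
        # independent k-means oracle on the same sample
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        want = np.sort(km.cluster_centers_.ravel())
        assert np.all(np.abs(got - want) < 3)
        assert np.all(np.abs(got - np.array([60, 180])) < 3)
        assert u.shape == (1000, 2)
        assert np.allclose(u.sum(axis=1), 1.0, atol=1e-10)

    def test_single_cluster_centre_is_sample_mean(self, rng):
        X = rng.uniform(0, 255, size=(50, 2))
        centers, u = fuzzy_c_means(X, 1, rng=np.random.default_rng(0))
        assert np.allclose(centers[0], X.mean(axis=0))
        assert np.all(u == 1.0)

    def test_constant_image_is_degenerate(self):
        img = np.full((8, 8), 77, dtype=np.uint8)
        features = extract_features(img)
        with pytest.raises(ValueError, match="feature 0"):
            fcm_initialize(features, AlgorithmConfig(n_clusters=2))

    def test_initialize_contract(self, noisy_two_region):
        noisy, _ = noisy_two_region
        features = extract_features(noisy)
        cfg = AlgorithmConfig(n_clusters=2, seed=3)
        params, state = fcm_initialize(features, cfg)
        N, D = features.values.shape
        assert params.mu.shape == (2, D)
        assert np.all(params.sigma2 >= cfg.variance_floor)
        assert np.allclose(params.eps, features.values.mean(axis=0))
        assert np.allclose(state.pi, 0.5)
        assert np.all(state.s == 0.5)
        assert np.allclose(state.z.sum(axis=1), 1.0, atol=1e-10)


# ---------------------------------------------------------------------------
# Block updates vs oracles
# ---------------------------------------------------------------------------

class TestDissimilarity:
    def test_full_saliency_drops_background(self, rng):
        features, params, state = random_instance(rng)
        s = np.ones_like(state.s)
        d = dissimilarity(features, params, s)
        want = -gaussian_log_pdf(features.values[:, None, :],
                                 params.mu[None], params.sigma2[None]).sum(2)
        assert np.allclose(d, want)

    def test_zero_saliency_is_class_independent(self, rng):
        features, params, state = random_instance(rng)
        d = dissimilarity(features, params, np.zeros_like(state.s))
        assert np.allclose(d, d[:, [0]])

    def test_scalar_hand_evaluation(self):
        # 1 pixel, 1 feature, 2 classes, evaluated term by term
        features = PixelFeatureMatrix(np.array([[100.0]]), (1, 1))
        params = ClusterParameters(
            mu=np.array([[90.0], [150.0]]), sigma2=np.array([[100.0], [400.0]]),
            eps=np.array([120.0]), nu2=np.array([900.0]), rho=np.array([0.5]))
        s = np.array([[[0.7], [0.2]]])
        d = dissimilarity(features, params, s)
        lc1 = math.log(1 / math.sqrt(2 * math.pi * 100)) - 100 / 200
        lc2 = math.log(1 / math.sqrt(2 * math.pi * 400)) - 2500 / 800
        lb = math.log(1 / math.sqrt(2 * math.pi * 900)) - 400 / 1800
        assert d[0, 0] == pytest.approx(-0.7 * lc1 - 0.3 * lb, rel=1e-12)
        assert d[0, 1] == pytest.approx(-0.2 * lc2 - 0.8 * lb, rel=1e-12)


class TestSaliencyUpdate:
    def test_symmetric_odds_give_half(self):
        features = PixelFeatureMatrix(np.array([[100.0]]), (1, 1))
        params = ClusterParameters(
            mu=np.array([[90.0]]), sigma2=np.array([[400.0]]),
            eps=np.array([90.0]), nu2=np.array([400.0]), rho=np.array([0.5]))
        s = update_saliency(features, params, AlgorithmConfig())
        assert np.allclose(s, 0.5)

    def test_large_gamma_flattens_to_prior(self, rng):
        features, params, _ = random_instance(rng)
        cfg = AlgorithmConfig(gamma=1e9)
        s = update_saliency(features, params, cfg)
        assert np.allclose(s, params.rho[None, None, :], atol=1e-6)

    def test_matches_grid_search_minimiser(self, rng):
        features, params, _ = random_instance(rng, H=2, W=3)
        cfg = AlgorithmConfig(gamma=15.0)
        s = update_saliency(features, params, cfg)
        for (i, j, l) in [(0, 0, 0), (3, 1, 1), (5, 2, 0)]:
            want = grid_min_saliency(
                features.values[i, l], params.mu[j, l], params.sigma2[j, l],
                params.eps[l], params.nu2[l], params.rho[l], cfg.gamma)
            assert abs(s[i, j, l] - want) <= 2e-4


class TestMembershipUpdate:
    def test_symmetry_gives_uniform(self):
        cfg = AlgorithmConfig(n_clusters=3)
        d = np.full((4, 3), 7.0)
        K = np.full((4, 3), 2.0)
        pi = np.full((4, 3), 1 / 3)
        z = update_membership(d, K, pi, cfg)
        assert np.allclose(z, 1 / 3)

    def test_infinite_lambda_returns_prior(self, rng):
        features, params, state = random_instance(rng)
        cfg = AlgorithmConfig(lam=1e12)
        d = dissimilarity(features, params, state.s)
        K = saliency_kl(state.s, params.rho)
        z = update_membership(d, K, state.pi, cfg)
        assert np.allclose(z, state.pi, atol=1e-8)

    def test_rows_sum_to_one_under_extreme_dissimilarity(self):
        cfg = AlgorithmConfig()
        d = np.array([[1e8, 2e8], [3.0, 4.0]])
        K = np.zeros((2, 2))
        pi = np.full((2, 2), 0.5)
        z = update_membership(d, K, pi, cfg)
        assert np.allclose(z.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(np.isfinite(z))

    def test_matches_grid_search_minimiser(self):
        cfg = AlgorithmConfig(lam=20.0, gamma=15.0)
        d = np.array([[5.0, 9.0]])
        K = np.array([[0.3, 0.1]])
        pi = np.array([[0.4, 0.6]])
        z = update_membership(d, K, pi, cfg)
        want = grid_min_membership(d[0], K[0], pi[0], cfg.lam, cfg.gamma)
        assert abs(z[0, 0] - want) <= 2e-4


class TestMomentUpdates:
    def test_hard_assignments_give_class_means(self, rng):
        X = rng.uniform(0, 255, size=(20, 1))
        labels = rng.integers(0, 2, size=20)
        z = np.eye(2)[labels]
        s = np.ones((20, 2, 1))
        features = PixelFeatureMatrix(X, (4, 5))
        mu, sigma2 = update_class_params(features, z, s)
        for j in range(2):
            assert mu[j, 0] == pytest.approx(X[labels == j, 0].mean())

    def test_single_pixel_floors_variance(self):
        features = PixelFeatureMatrix(np.array([[42.0]]), (1, 1))
        mu, sigma2 = update_class_params(
            features, np.array([[1.0]]), np.ones((1, 1, 1)),
            variance_floor=1e-4)
        assert mu[0, 0] == 42.0
        assert sigma2[0, 0] == 1e-4

    def test_class_moments_match_bruteforce_loop(self, rng):
        features, params, state = random_instance(rng, H=4, W=5)
        mu, sigma2 = update_class_params(features, state.z, state.s,
                                         variance_floor=1e-12)
        mu_o, sig_o = naive_class_moments(features.values, state.z, state.s)
        assert np.allclose(mu, mu_o, rtol=1e-10)
        assert np.allclose(sigma2, sig_o, rtol=1e-10)

    def test_background_zero_saliency_gives_global_mean(self, rng):
        features, params, state = random_instance(rng)
        s = np.zeros_like(state.s)
        eps, nu2 = update_background_params(features, state.z, s)
        assert np.allclose(eps, features.values.mean(axis=0))

    def test_background_moments_match_bruteforce_loop(self, rng):
        features, params, state = random_instance(rng, H=4, W=5)
        eps, nu2 = update_background_params(features, state.z, state.s,
                                            variance_floor=1e-12)
        eps_o, nu_o = naive_background_moments(features.values, state.z, state.s)
        assert np.allclose(eps, eps_o, rtol=1e-10)
        assert np.allclose(nu2, nu_o, rtol=1e-10)

    def test_background_guard_on_full_saliency(self, rng):
        features, params, state = random_instance(rng)
        s = np.ones_like(state.s)
        with pytest.warns(RuntimeWarning):
            eps, nu2 = update_background_params(features, state.z, s,
                                                prev=params)
        assert np.allclose(eps, params.eps)

    def test_saliency_prior_cases(self, rng):
        features, params, state = random_instance(rng)
        assert np.allclose(
            update_saliency_prior(state.z, np.ones_like(state.s)),
            1 - 1e-3)
        assert np.allclose(
            update_saliency_prior(state.z, np.full_like(state.s, 0.5)), 0.5)
        rho = update_saliency_prior(state.z, state.s)
        assert np.allclose(rho, naive_saliency_prior(state.z, state.s),
                           rtol=1e-10)


class TestStationarity:
    """Each closed-form update zeroes the analytic partial derivative."""

    def test_parameter_updates_zero_their_gradients(self, rng):
        features, params, state = random_instance(rng, H=4, W=5)
        X, z, s = features.values, state.z, state.s
        mu, sigma2 = update_class_params(features, z, s, variance_floor=1e-12)
        # dJ/dmu_jl = sum_i z s (mu - x)/sigma2
        grad_mu = (z[:, :, None] * s * (mu[None] - X[:, None, :])).sum(0) / sigma2
        scale = (z[:, :, None] * s * (np.abs(X)[:, None, :] + np.abs(mu[None]))
                 ).sum(0) / sigma2
        assert np.all(np.abs(grad_mu) <= 1e-6 * scale)
        # dJ/dsigma2 = 0.5 sum_i z s (1/sigma2 - (x-mu)^2/sigma2^2)
        grad_s2 = 0.5 * (z[:, :, None] * s
                         * (1 / sigma2[None]
                            - (X[:, None, :] - mu[None]) ** 2
                            / sigma2[None] ** 2)).sum(0)
        assert np.all(np.abs(grad_s2 * sigma2) <= 1e-6 * (z[:, :, None] * s).sum(0))
        eps, nu2 = update_background_params(features, z, s,
                                            variance_floor=1e-12)
        w = (z[:, :, None] * (1 - s)).sum(1)
        grad_eps = (w * (eps[None] - X)).sum(0) / nu2
        assert np.all(np.abs(grad_eps) <= 1e-6 * (w * np.abs(X)).sum(0) / nu2)
        # rho stationarity of the Lagrangian: rho = sum z s / N
        rho = update_saliency_prior(z, s, rho_floor=1e-6)
        resid = (z[:, :, None] * (s / rho[None, None]
                                  - (1 - s) / (1 - rho[None, None]))).sum((0, 1))
        assert np.all(np.abs(resid) <= 1e-6 * z.shape[0])


class TestObjective:
    def test_kl_term_vanishes_when_z_and_g_equal_prior(self, rng):
        features, params, state = random_instance(rng)
        state.z = state.pi.copy()
        state.G = state.pi.copy()
        cfg = AlgorithmConfig(n_clusters=3, lam=150.0)
        full = objective(features, params, state, cfg)
        d = dissimilarity(features, params, state.s)
        K = saliency_kl(state.s, params.rho)
        assert full == pytest.approx(float((state.z * d).sum()
                                           + cfg.gamma * (state.z * K).sum()))

    def test_single_pixel_term_by_term(self):
        features = PixelFeatureMatrix(np.array([[100.0]]), (1, 1))
        params = ClusterParameters(
            mu=np.array([[90.0], [150.0]]), sigma2=np.array([[100.0], [400.0]]),
            eps=np.array([120.0]), nu2=np.array([900.0]), rho=np.array([0.6]))
        state = MembershipState(
            z=np.array([[0.7, 0.3]]), s=np.array([[[0.8], [0.4]]]),
            pi=np.array([[0.55, 0.45]]), G=np.array([[1.2, 1.1]]))
        cfg = AlgorithmConfig(lam=150.0, gamma=15.0)
        got = objective(features, params, state, cfg)
        # independent scalar evaluation
        def lpdf(x, m, v):
            return math.log(1 / math.sqrt(2 * math.pi * v)) - (x - m) ** 2 / (2 * v)
        lb = lpdf(100, 120, 900)
        d = [-0.8 * lpdf(100, 90, 100) - 0.2 * lb,
             -0.4 * lpdf(100, 150, 400) - 0.6 * lb]
        kl = [0.8 * math.log(0.8 / 0.6) + 0.2 * math.log(0.2 / 0.4),
              0.4 * math.log(0.4 / 0.6) + 0.6 * math.log(0.6 / 0.4)]
        want = (0.7 * d[0] + 0.3 * d[1]
                + 150.0 * (0.7 * math.log(0.7 / 0.55)
                           + 0.3 * math.log(0.3 / 0.45)
                           + 1.2 * math.log(1.2 / 0.55)
                           + 1.1 * math.log(1.1 / 0.45))
                + 15.0 * (0.7 * kl[0] + 0.3 * kl[1]))
        assert got == pytest.approx(want, rel=1e-12)

    def test_sweep_with_frozen_prior_never_increases(self, rng):
        """Alternating minimisation: one s/z/parameter sweep with pi and G
        held fixed must not increase the objective."""
        cfg = AlgorithmConfig(n_clusters=3, lam=20.0, gamma=5.0,
                              variance_floor=1e-8, rho_floor=1e-8)
        features, params, state = random_instance(rng, H=4, W=5)
        values = [objective(features, params, state, cfg)]

        state.s = update_saliency(features, params, cfg)
        values.append(objective(features, params, state, cfg))
        d = dissimilarity(features, params, state.s)
        K = saliency_kl(state.s, params.rho)
        state.z = update_membership(d, K, state.pi, cfg)
        values.append(objective(features, params, state, cfg))
        params.mu, params.sigma2 = update_class_params(
            features, state.z, state.s, prev=params,
            variance_floor=cfg.variance_floor)
        values.append(objective(features, params, state, cfg))
        params.eps, params.nu2 = update_background_params(
            features, state.z, state.s, prev=params,
            variance_floor=cfg.variance_floor)
        values.append(objective(features, params, state, cfg))
        params.rho = update_saliency_prior(state.z, state.s, cfg.rho_floor)
        values.append(objective(features, params, state, cfg))
        diffs = np.diff(values)
        assert np.all(diffs <= 1e-8 * np.abs(values[0]))


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

class TestRunSegmentation:
    def test_noiseless_two_level_matches_threshold_oracle(self):
        from saliencyfcm.synthetic import make_phantom
        from saliencyfcm.metrics import mcr
        ph = make_phantom("two_region", 48, 48, levels=(60, 180))
        # a 3x3 window suits noise-free input; wide windows erode the
        # rasterised disk's extreme corner pixels
        cfg = AlgorithmConfig(n_clusters=2, seed=0, max_iter=150, window=3)
        result = run_segmentation(ph.clean, cfg)
        oracle = (ph.clean > 120).astype(int)  # midlevel threshold
        rate, _, _ = mcr(result.labels, oracle)
        assert rate == 0.0
        assert result.labels.shape == (48, 48)
        assert len(result.objective_trace) == result.iterations

    def test_constant_image_rejected(self):
        img = np.full((40, 40), 128, dtype=np.uint8)
        with pytest.raises(ValueError, match="distinct grey levels"):
            run_segmentation(img, AlgorithmConfig(n_clusters=2))

    def test_too_many_clusters_rejected(self):
        img = np.tile(np.array([10, 200], dtype=np.uint8), (32, 16))
        with pytest.raises(ValueError, match="distinct grey levels"):
            run_segmentation(img, AlgorithmConfig(n_clusters=3))

    def test_same_seed_is_bit_identical(self, noisy_two_region):
        noisy, _ = noisy_two_region
        cfg = AlgorithmConfig(n_clusters=2, seed=11, max_iter=40)
        a = run_segmentation(noisy, cfg)
        b = run_segmentation(noisy, cfg)
        assert np.array_equal(a.labels, b.labels)
        assert a.objective_trace == b.objective_trace

    def test_permuting_initial_classes_permutes_labels(self, noisy_two_region):
        noisy, _ = noisy_two_region
        cfg = AlgorithmConfig(n_clusters=2, seed=0, max_iter=40)
        a = run_segmentation(noisy, cfg,
                             init_centers=np.array([[60.0], [180.0]]))
        b = run_segmentation(noisy, cfg,
                             init_centers=np.array([[180.0], [60.0]]))
        assert np.array_equal(b.labels, 1 - a.labels)

    def test_two_feature_mode_runs(self, noisy_two_region):
        noisy, ph = noisy_two_region
        from saliencyfcm.metrics import mcr
        cfg = AlgorithmConfig(n_clusters=2, seed=1, max_iter=60,
                              features="intensity_mean")
        result = run_segmentation(noisy, cfg)
        rate, _, _ = mcr(result.labels, ph.truth)
        assert rate < 5.0

    def test_tie_breaking_prefers_lowest_index(self):
        z = np.array([[0.5, 0.5], [0.2, 0.8]])
        assert z.argmax(axis=1).tolist() == [0, 1]


class TestFeatureExtraction:
    def test_intensity_mean_stays_in_range(self, rng):
        img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        f = extract_features(img, mode="intensity_mean")
        assert f.values.shape == (256, 2)
        assert f.values.min() >= 0 and f.values.max() <= 255

    def test_rejects_float_image(self):
        with pytest.raises(ValueError, match="8-bit"):
            extract_features(np.zeros((8, 8), dtype=float))
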