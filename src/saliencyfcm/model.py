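"""Feature-saliency fuzzy Gaussian-mixture solver with spatial constraints.

The model clusters per-pixel feature vectors x_il (i = 1..N pixels,
l = 1..D features) into C classes. Each feature is either *salient* —
drawn from a class-specific Gaussian N(mu_jl, sigma2_jl) — or background,
drawn from a class-independent Gaussian N(eps_l, nu2_l); rho_l is the prior
probability that feature l is salient and s_ijl its per-pixel, per-class
posterior. Memberships z_ij are tied to a spatial prior pi_ij through a
KL penalty weighted by lam; pi itself combines the previous memberships
with a neighbourhood-driven noise smoothing factor G_ij, which is what
suppresses isolated noise pixels.

The objective minimised by block-coordinate descent is

    J = sum_ij z_ij d_ij
        + lam * sum_ij [ z_ij log(z_ij/pi_ij) + G_ij log(G_ij/pi_ij) ]
        + gamma * sum_ij z_ij KL(s_ij. || rho)

with d_ij the saliency-weighted negative log-likelihood

    d_ij = sum_l [ -s_ijl log N(x_il; mu_jl, sigma2_jl)
                   - (1 - s_ijl) log N(x_il; eps_l, nu2_l) ].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, rel_entr

from .config import AlgorithmConfig
from .neighborhood import (NeighborhoodSystem, box_sum, combined_prior,
                           markov_prior, neighbor_class_weights,
                           smoothing_factor)

logger = logging.getLogger(__name__)

PROB_CLIP = 1e-10
LOG_CLIP = 1e-300
WEIGHT_GUARD = 1e-12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PixelFeatureMatrix:
    """Per-pixel feature vectors on an H x W grid, row-major pixel order."""

    values: np.ndarray          # (N, D) float
    grid_shape: tuple[int, int]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (N, D)")
        H, W = self.grid_shape
        if self.values.shape[0] != H * W:
            raise ValueError(f"N = {self.values.shape[0]} does not match "
                             f"grid {H}x{W}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusterParameters:
    """Gaussian parameters of the salient (per-class) and background models."""

    mu: np.ndarray      # (C, D) class means
    sigma2: np.ndarray  # (C, D) class variances
    eps: np.ndarray     # (D,)  background means
    nu2: np.ndarray     # (D,)  background variances
    rho: np.ndarray     # (D,)  feature-saliency priors in (0, 1)


@dataclass
class MembershipState:
    """All per-pixel soft assignments of the solver."""

    z: np.ndarray   # (N, C) classification memberships, rows sum to 1
    s: np.ndarray   # (N, C, D) saliency memberships in (0, 1)
    pi: np.ndarray  # (N, C) prior probabilities, rows sum to 1
    G: np.ndarray   # (N, C) noise smoothing factors, >= 1


@dataclass
class SegmentationResult:
    labels: np.ndarray  # (H, W) int labels in [0, C)
    state: MembershipState
    params: ClusterParameters
    objective_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_features(image: np.ndarray, mode: str = "intensity",
                     mean_window: int = 3) -> PixelFeatureMatrix:
    """Build the pixel feature matrix from an 8-bit greyscale image.

    "intensity" uses the raw grey level (D = 1). "intensity_mean"
    appends the replicate-padded window mean of the grey level (D = 2);
    both features stay within [0, 255].
    """
    img = _validate_image(image)
    cols = [img.astype(float).ravel()]
    if mode == "intensity_mean":
        cols.append((box_sum(img.astype(float), mean_window)
                     / (mean_window * mean_window)).ravel())
    elif mode != "intensity":
        raise ValueError(f"unknown feature mode {mode!r}")
    return PixelFeatureMatrix(np.column_stack(cols), img.shape)


def _validate_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D greyscale image, got shape {img.shape}")
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError(f"expected an 8-bit integer image, got dtype {img.dtype}")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("image values must lie in [0, 255]")
    return img


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def gaussian_log_pdf(x, mean, var):
    """Log of the univariate normal density; broadcasts over its arguments."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(mean))
            and np.all(np.isfinite(var))):
        raise ValueError("non-finite input to gaussian_log_pdf "
                         "(corrupt feature or parameter)")
    if np.any(var <= 0):
        raise ValueError("variance must be positive")
    return -0.5 * np.log(2.0 * np.pi * var) - (x - mean) ** 2 / (2.0 * var)


def _log_densities(features: PixelFeatureMatrix, params: ClusterParameters):
    """Class and background log-densities for every pixel/class/feature.

    Returns ``(log_class, log_bg)`` with shapes (N, C, D) and (N, D).
    """
    x = features.values  # (N, D)
    log_class = gaussian_log_pdf(x[:, None, :], params.mu[None, :, :],
                                 params.sigma2[None, :, :])
    log_bg = gaussian_log_pdf(x, params.eps[None, :], params.nu2[None, :])
    return log_class, log_bg


# ---------------------------------------------------------------------------
# FCM initialisation
# ---------------------------------------------------------------------------

def fuzzy_c_means(X: np.ndarray, n_clusters: int, m: float = 2.0,
                  rng: np.random.Generator | None = None,
                  init_centers: np.ndarray | None = None,
                  max_iter: int = 100, tol: float = 1e-6):
    """Plain fuzzy C-means on an (N, D) sample matrix.

    Centres are initialised from ``init_centers`` or by drawing
    ``n_clusters`` distinct unique rows with ``rng``. Returns
    ``(centers, memberships)``.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    if N < n_clusters:
        raise ValueError(f"need at least {n_clusters} samples, got {N}")
    if init_centers is not None:
        centers = np.asarray(init_centers, dtype=float).copy()
        if centers.shape != (n_clusters, X.shape[1]):
            raise ValueError("init_centers has wrong shape")
    else:
        if rng is None:
            rng = np.random.default_rng()
        uniq = np.unique(X, axis=0)
        if uniq.shape[0] < n_clusters:
            raise ValueError(
                f"only {uniq.shape[0]} distinct feature vectors available "
                f"for {n_clusters} clusters")
        centers = uniq[rng.choice(uniq.shape[0], size=n_clusters,
                                  replace=False)]
    expo = -1.0 / (m - 1.0)
    u = np.full((N, n_clusters), 1.0 / n_clusters)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        w = d2 ** expo
        u = w / w.sum(axis=1, keepdims=True)
        um = u ** m
        new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    return centers, u


def fcm_initialize(features: PixelFeatureMatrix, config: AlgorithmConfig,
                   init_centers: np.ndarray | None = None):
    """Initialise all parameters and memberships from a fuzzy C-means run.

    Class moments are z-weighted; background moments are the global
    per-feature moments; rho_l = 1/D (clipped), s = 1/2, pi = 1/C.
    """
    X = features.values
    ptp = X.max(axis=0) - X.min(axis=0)
    if np.any(ptp == 0):
        bad = int(np.argmin(ptp))
        raise ValueError(
            f"feature {bad} is constant across all pixels; "
            "the image is degenerate for clustering")
    rng = np.random.default_rng(config.seed)
    _, z = fuzzy_c_means(X, config.n_clusters, m=config.fcm_fuzzifier,
                         rng=rng, init_centers=init_centers)
    wsum = z.sum(axis=0)  # (C,)
    mu = (z.T @ X) / wsum[:, None]
    sigma2 = np.empty_like(mu)
    for j in range(config.n_clusters):
        sigma2[j] = (z[:, j][:, None] * (X - mu[j]) ** 2).sum(axis=0) / wsum[j]
    sigma2 = np.maximum(sigma2, config.variance_floor)
    eps = X.mean(axis=0)
    nu2 = np.maximum(X.var(axis=0), config.variance_floor)
    D = features.n_features
    rho = np.clip(np.full(D, 1.0 / D), config.rho_floor, 1.0 - config.rho_floor)
    params = ClusterParameters(mu=mu, sigma2=sigma2, eps=eps, nu2=nu2, rho=rho)
    N, C = z.shape
    state = MembershipState(
        z=z,
        s=np.full((N, C, D), 0.5),
        pi=np.full((N, C), 1.0 / C),
        G=np.ones((N, C)),
    )
    return params, state


# ---------------------------------------------------------------------------
# Block-coordinate updates
# ---------------------------------------------------------------------------

def update_saliency(features: PixelFeatureMatrix, params: ClusterParameters,
                    config: AlgorithmConfig) -> np.ndarray:
    """Saliency posterior with symmetric 1/gamma tempering of both densities.

    s_ijl = rho_l Phi_jl^(1/gamma) /
            (rho_l Phi_jl^(1/gamma) + (1-rho_l) Phi_l^(1/gamma)),
    computed in log space and clipped to (0, 1).
    """
    log_class, log_bg = _log_densities(features, params)
    a = np.log(params.rho)[None, None, :] + log_class / config.gamma
    b = np.log1p(-params.rho)[None, None, :] + log_bg[:, None, :] / config.gamma
    return np.clip(expit(a - b), PROB_CLIP, 1.0 - PROB_CLIP)


def dissimilarity(features: PixelFeatureMatrix, params: ClusterParameters,
                  s: np.ndarray) -> np.ndarray:
    """Saliency-weighted negative log-likelihood d_ij, shape (N, C)."""
    log_class, log_bg = _log_densities(features, params)
    return (-s * log_class - (1.0 - s) * log_bg[:, None, :]).sum(axis=2)


def saliency_kl(s: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Per-pixel, per-class KL divergence of the saliency memberships
    from the saliency prior: K_ij = sum_l KL(Bern(s_ijl) || Bern(rho_l))."""
    r = rho[None, None, :]
    return (rel_entr(s, r) + rel_entr(1.0 - s, 1.0 - r)).sum(axis=2)


def update_membership(d: np.ndarray, K: np.ndarray, pi: np.ndarray,
                      config: AlgorithmConfig) -> np.ndarray:
    """Gibbs/softmax membership update.

    z_ij is proportional to pi_ij * exp(-(d_ij + gamma K_ij)/lam),
    row-normalised via a log-sum-exp shift so no pixel underflows to an
    all-zero row.
    """
    logits = np.log(np.clip(pi, LOG_CLIP, None)) - (d + config.gamma * K) / config.lam
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return w / w.sum(axis=1, keepdims=True)


def update_class_params(features: PixelFeatureMatrix, z: np.ndarray,
                        s: np.ndarray, prev: ClusterParameters | None = None,
                        variance_floor: float = 1e-4):
    """Weighted-moment update of class means and variances.

    Normaliser M_jl = sum_i z_ij s_ijl. A class/feature pair whose weight
    mass falls below a tiny guard keeps its previous parameters.
    """
    X = features.values
    w = z[:, :, None] * s               # (N, C, D)
    M = w.sum(axis=0)                   # (C, D)
    ok = M > WEIGHT_GUARD
    safe_M = np.where(ok, M, 1.0)
    mu = (w * X[:, None, :]).sum(axis=0) / safe_M
    sigma2 = (w * (X[:, None, :] - mu[None]) ** 2).sum(axis=0) / safe_M
    if not np.all(ok):
        if prev is None:
            raise ValueError("empty class/feature weight mass and no previous "
                             "parameters to fall back on")
        warnings.warn("class/feature pair(s) with vanishing weight mass kept "
                      "their previous parameters", RuntimeWarning)
        mu = np.where(ok, mu, prev.mu)
        sigma2 = np.where(ok, sigma2, prev.sigma2)
    return mu, np.maximum(sigma2, variance_floor)


def update_background_params(features: PixelFeatureMatrix, z: np.ndarray,
                             s: np.ndarray,
                             prev: ClusterParameters | None = None,
                             variance_floor: float = 1e-4):
    """Weighted-moment update of background means and variances.

    Normaliser F_l = sum_ij z_ij (1 - s_ijl); vanishing mass keeps the
    previous values.
    """
    X = features.values
    w = (z[:, :, None] * (1.0 - s)).sum(axis=1)  # (N, D)
    F = w.sum(axis=0)                            # (D,)
    ok = F > WEIGHT_GUARD
    safe_F = np.where(ok, F, 1.0)
    eps = (w * X).sum(axis=0) / safe_F
    nu2 = (w * (X - eps[None]) ** 2).sum(axis=0) / safe_F
    if not np.all(ok):
        if prev is None:
            raise ValueError("empty background weight mass and no previous "
                             "parameters to fall back on")
        warnings.warn("background feature(s) with vanishing weight mass kept "
                      "their previous parameters", RuntimeWarning)
        eps = np.where(ok, eps, prev.eps)
        nu2 = np.where(ok, nu2, prev.nu2)
    return eps, np.maximum(nu2, variance_floor)


def update_saliency_prior(z: np.ndarray, s: np.ndarray,
                          rho_floor: float = 1e-3) -> np.ndarray:
    """rho_l = (1/N) sum_ij z_ij s_ijl, clipped away from {0, 1}."""
    N = z.shape[0]
    rho = (z[:, :, None] * s).sum(axis=(0, 1)) / N
    return np.clip(rho, rho_floor, 1.0 - rho_floor)


def objective(features: PixelFeatureMatrix, params: ClusterParameters,
              state: MembershipState, config: AlgorithmConfig) -> float:
    """Full objective J; 0*log 0 := 0, log arguments clipped at 1e-300."""
    d = dissimilarity(features, params, state.s)
    pic = np.clip(state.pi, LOG_CLIP, None)
    z = state.z
    zterm = np.where(z > 0, z * np.log(np.clip(z, LOG_CLIP, None) / pic), 0.0).sum()
    gterm = (state.G * np.log(state.G / pic)).sum()
    K = saliency_kl(state.s, params.rho)
    return float((z * d).sum() + config.lam * (zterm + gterm)
                 + config.gamma * (z * K).sum())


# ---------------------------------------------------------------------------
# Outer loop
# ---------------------------------------------------------------------------

def run_segmentation(image: np.ndarray, config: AlgorithmConfig,
                     init_centers: np.ndarray | None = None,
                     callback=None) -> SegmentationResult:
    """Segment an 8-bit greyscale image.

    Runs FCM initialisation followed by block-coordinate descent:
    per outer iteration the smoothing factor G, the combined prior pi,
    the saliency memberships s, the classification memberships z and all
    Gaussian/saliency parameters are refreshed in that order, and the
    objective is recorded. Iteration stops when the absolute objective
    decrease falls below ``config.delta`` or after ``config.max_iter``
    sweeps. ``callback(iteration, params, state, objective)`` is invoked
    after every sweep when given.
    """
    config.validate()
    img = _validate_image(image)
    if np.unique(img).size < config.n_clusters:
        raise ValueError(
            f"image has {np.unique(img).size} distinct grey levels, "
            f"fewer than n_clusters={config.n_clusters}")
    features = extract_features(img, mode=config.features)
    params, state = fcm_initialize(features, config, init_centers=init_centers)
    sys = NeighborhoodSystem(config.window)

    trace: list[float] = []
    converged = False
    t = 0
    for t in range(1, config.max_iter + 1):
        h = neighbor_class_weights(features, params, sys, config.alpha)
        h_norm = markov_prior(h)
        state.G = smoothing_factor(state.z, h_norm, sys, config.beta,
                                   features.grid_shape)
        state.pi = combined_prior(state.z, state.G)
        state.s = update_saliency(features, params, config)
        d = dissimilarity(features, params, state.s)
        K = saliency_kl(state.s, params.rho)
        prev_mu = params.mu
        state.z = update_membership(d, K, state.pi, config)
        params.mu, params.sigma2 = update_class_params(
            features, state.z, state.s, prev=params,
            variance_floor=config.variance_floor)
        params.eps, params.nu2 = update_background_params(
            features, state.z, state.s, prev=params,
            variance_floor=config.variance_floor)
        params.rho = update_saliency_prior(state.z, state.s, config.rho_floor)
        L = objective(features, params, state, config)
        trace.append(L)
        logger.debug("iter %d  objective %.6f  max|dmu| %.4g",
                     t, L, float(np.abs(params.mu - prev_mu).max()))
        if callback is not None:
            callback(t, params, state, L)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < config.delta:
            converged = True
            break

    labels = state.z.argmax(axis=1).reshape(features.grid_shape)
    return SegmentationResult(labels=labels, state=state, params=params,
                              objective_trace=trace, iterations=t,
                              converged=converged)
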