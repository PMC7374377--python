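"""Scikit-learn style estimators over the segmentation solver.

``SaliencyFuzzySegmenter`` is the neighbourhood-constrained feature-saliency
clustering segmenter; ``FuzzyCMeans`` is the plain FCM baseline it is
compared against. Both take a 2-D 8-bit greyscale image in ``fit`` and
expose the label map as ``labels_``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from . import model
from .config import AlgorithmConfig


class SaliencyFuzzySegmenter(ClusterMixin, BaseEstimator):
    """Noise-robust fuzzy clustering image segmenter.

    Feature-saliency Gaussian mixture clustering with a Markov
    neighbourhood prior, a noise smoothing factor and KL-regularised
    memberships, solved by block-coordinate descent after a fuzzy
    C-means initialisation.

    Parameters mirror :class:`~saliencyfcm.config.AlgorithmConfig`;
    ``random_state`` seeds the FCM centre initialisation (the only
    stochastic step).

    Attributes
    ----------
    labels_ : ndarray of shape (H, W)
        Per-pixel class labels (argmax membership, ties to lowest index).
    cluster_means_ : ndarray of shape (C, D)
        Converged class means mu_jl.
    cluster_variances_ : ndarray of shape (C, D)
        Converged class variances sigma2_jl.
    background_means_, background_variances_ : ndarray of shape (D,)
        Converged background Gaussian parameters eps_l, nu2_l.
    saliency_prior_ : ndarray of shape (D,)
        Converged feature-saliency priors rho_l.
    membership_ : ndarray of shape (N, C)
        Final classification memberships z_ij (row-major pixels).
    objective_trace_ : list of float
        Objective value after each outer iteration.
    n_iter_ : int
        Number of outer iterations performed.
    converged_ : bool
        Whether the objective-decrease threshold was met before max_iter.

    Examples
    --------
    >>> from saliencyfcm.synthetic import make_phantom
    >>> ph = make_phantom("two_region", 64, 64, levels=(60, 180))
    >>> seg = SaliencyFuzzySegmenter(n_clusters=2, random_state=0).fit(ph.clean)
    >>> seg.labels_.shape
    (64, 64)
    """

    def __init__(self, n_clusters: int = 2, window: int = 5,
                 lam: float = 150.0, gamma: float = 15.0, beta: float = 12.0,
                 alpha: float = 2.0, delta: float = 1e-4, max_iter: int = 400,
                 random_state: int = 0, variance_floor: float = 1e-4,
                 rho_floor: float = 1e-3, fcm_fuzzifier: float = 2.0,
                 features: str = "intensity"):
        self.n_clusters = n_clusters
        self.window = window
        self.lam = lam
        self.gamma = gamma
        self.beta = beta
        self.alpha = alpha
        self.delta = delta
        self.max_iter = max_iter
        self.random_state = random_state
        self.variance_floor = variance_floor
        self.rho_floor = rho_floor
        self.fcm_fuzzifier = fcm_fuzzifier
        self.features = features

    def _config(self) -> AlgorithmConfig:
        return AlgorithmConfig(
            n_clusters=self.n_clusters, window=self.window, lam=self.lam,
            gamma=self.gamma, beta=self.beta, alpha=self.alpha,
            delta=self.delta, max_iter=self.max_iter, seed=self.random_state,
            variance_floor=self.variance_floor, rho_floor=self.rho_floor,
            fcm_fuzzifier=self.fcm_fuzzifier, features=self.features)

    def fit(self, X, y=None, init_centers=None, callback=None):
        """Segment the image ``X`` (2-D, 8-bit greyscale)."""
        result = model.run_segmentation(X, self._config(),
                                        init_centers=init_centers,
                                        callback=callback)
        self.result_ = result
        self.labels_ = result.labels
        self.cluster_means_ = result.params.mu
        self.cluster_variances_ = result.params.sigma2
        self.background_means_ = result.params.eps
        self.background_variances_ = result.params.nu2
        self.saliency_prior_ = result.params.rho
        self.membership_ = result.state.z
        self.objective_trace_ = result.objective_trace
        self.n_iter_ = result.iterations
        self.converged_ = result.converged
        return self

    def predict(self, X):
        """Label a new image with the fitted Gaussian parameters.

        Uses the converged class/background models and saliency prior with
        a uniform class prior (no spatial coupling to the training image).
        """
        if not hasattr(self, "result_"):
            raise RuntimeError("fit must be called before predict")
        config = self._config()
        features = model.extract_features(np.asarray(X), mode=self.features)
        params = self.result_.params
        s = model.update_saliency(features, params, config)
        d = model.dissimilarity(features, params, s)
        K = model.saliency_kl(s, params.rho)
        pi = np.full(d.shape, 1.0 / self.n_clusters)
        z = model.update_membership(d, K, pi, config)
        return z.argmax(axis=1).reshape(features.grid_shape)


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Plain fuzzy C-means baseline segmenter on per-pixel intensity.

    No spatial information: each pixel is clustered independently by the
    classical FCM objective with fuzzifier ``m``.

    Attributes
    ----------
    labels_ : ndarray of shape (H, W)
    cluster_centers_ : ndarray of shape (C, D)
    membership_ : ndarray of shape (N, C)
    """

    def __init__(self, n_clusters: int = 2, m: float = 2.0,
                 max_iter: int = 100, tol: float = 1e-6,
                 random_state: int = 0, features: str = "intensity"):
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.features = features

    def fit(self, X, y=None):
        features = model.extract_features(np.asarray(X), mode=self.features)
        rng = np.random.default_rng(self.random_state)
        centers, u = model.fuzzy_c_means(
            features.values, self.n_clusters, m=self.m, rng=rng,
            max_iter=self.max_iter, tol=self.tol)
        self.cluster_centers_ = centers
        self.membership_ = u
        self.labels_ = u.argmax(axis=1).reshape(features.grid_shape)
        return self

    def predict(self, X):
        if not hasattr(self, "cluster_centers_"):
            raise RuntimeError("fit must be called before predict")
        features = model.extract_features(np.asarray(X), mode=self.features)
        d2 = ((features.values[:, None, :]
               - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1).reshape(features.grid_shape)
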