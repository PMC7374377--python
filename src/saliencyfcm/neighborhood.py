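"""Sliding-window spatial machinery for the segmenter.

All operators act on per-pixel fields stored row-major (pixel i = r*W + c)
and use replicate padding at the image border, so every pixel sees a full
w x w neighbourhood that includes the centre pixel itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

_DENSITY_FLOOR = 1e-300


@dataclass(frozen=True)
class NeighborhoodSystem:
    """Square w x w neighbourhood, centre included, replicate padding."""

    window: int = 5

    def __post_init__(self):
        if self.window % 2 != 1 or self.window < 1:
            raise ValueError(f"window must be a positive odd integer, got {self.window}")

    @property
    def n_i(self) -> int:
        """Number of pixels per neighbourhood (w^2, centre included)."""
        return self.window * self.window

    @property
    def offsets(self) -> list[tuple[int, int]]:
        r = self.window // 2
        return [(dr, dc) for dr in range(-r, r + 1) for dc in range(-r, r + 1)]


def box_sum(field: np.ndarray, window: int) -> np.ndarray:
    """Windowed sum of a 2-D field with replicate padding."""
    return uniform_filter(np.asarray(field, dtype=float), size=window,
                          mode="nearest") * (window * window)


def neighbor_class_weights(features, params, sys: NeighborhoodSystem,
                           alpha: float = 2.0) -> np.ndarray:
    """Windowed class-likelihood weights h_ijl.

    For every pixel i, class j and feature l, sums the Gaussian class
    likelihoods of the neighbouring feature values over the window and
    raises the sum to ``alpha``. Returns an (N, C, D) array floored at a
    tiny positive value so downstream normalisations stay defined.
    """
    from .model import _log_densities  # local import: avoid cycle

    H, W = features.grid_shape
    log_class, _ = _log_densities(features, params)  # (N, C, D)
    phi = np.exp(log_class)
    C, D = params.mu.shape
    h = np.empty_like(phi)
    for j in range(C):
        for l in range(D):
            h[:, j, l] = box_sum(phi[:, j, l].reshape(H, W), sys.window).ravel()
    return np.maximum(h ** alpha, _DENSITY_FLOOR)


def markov_prior(h: np.ndarray) -> np.ndarray:
    """Class prior from neighbourhood weights: feature-summed, class-normalised.

    pi_ij = sum_l h_ijl / sum_k sum_l h_ikl; rows sum to 1.
    """
    num = h.sum(axis=2)
    return num / num.sum(axis=1, keepdims=True)


def smoothing_factor(z: np.ndarray, h_norm: np.ndarray, sys: NeighborhoodSystem,
                     beta: float, grid_shape: tuple[int, int]) -> np.ndarray:
    """Noise smoothing factor G_ij = exp(beta/(2 N_i) * sum_t [z_tj + h_tj]).

    ``h_norm`` is the class-normalised neighbourhood weight (markov_prior
    output), so each bracketed term lies in [0, 2] and G in [1, e^beta].
    The exponent is clipped to [0, beta] to keep that range exact under
    box-filter round-off.
    """
    H, W = grid_shape
    field = z + h_norm
    C = z.shape[1]
    expo = np.empty_like(z)
    for j in range(C):
        expo[:, j] = box_sum(field[:, j].reshape(H, W), sys.window).ravel()
    expo *= beta / (2.0 * sys.n_i)
    np.clip(expo, 0.0, beta, out=expo)
    return np.exp(expo)


def combined_prior(z: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Prior combining membership and smoothing factor: (z + G) row-normalised."""
    t = z + G
    return t / t.sum(axis=1, keepdims=True)
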