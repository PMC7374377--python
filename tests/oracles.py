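"""Independent brute-force oracles used by the tests.

Everything here is deliberately written as explicit Python loops (or
exhaustive enumeration / grid search) so it shares no code path with the
vectorised implementations it checks.
"""

import itertools
import math

import numpy as np

from saliencyfcm.model import ClusterParameters, MembershipState, PixelFeatureMatrix


# ---------------------------------------------------------------------------
# Windowed operators, replicate padding, nested loops
# ---------------------------------------------------------------------------

def naive_box_sum(field, window):
    field = np.asarray(field, dtype=float)
    r = window // 2
    padded = np.pad(field, r, mode="edge")
    H, W = field.shape
    out = np.zeros_like(field)
    for i in range(H):
        for j in range(W):
            total = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    total += padded[i + r + di, j + r + dj]
            out[i, j] = total
    return out


def naive_neighbor_class_weights(features, params, window, alpha):
    H, W = features.grid_shape
    C, D = params.mu.shape
    h = np.zeros((H * W, C, D))
    for j in range(C):
        for l in range(D):
            dens = np.zeros((H, W))
            for i in range(H * W):
                x = features.values[i, l]
                mu, var = params.mu[j, l], params.sigma2[j, l]
                dens[i // W, i % W] = (
                    math.exp(-(x - mu) ** 2 / (2 * var))
                    / math.sqrt(2 * math.pi * var))
            h[:, j, l] = naive_box_sum(dens, window).ravel()
    return np.maximum(h ** alpha, 1e-300)


def naive_markov_prior(h):
    N, C, D = h.shape
    pi = np.zeros((N, C))
    for i in range(N):
        den = sum(h[i, k, l] for k in range(C) for l in range(D))
        for j in range(C):
            pi[i, j] = sum(h[i, j, l] for l in range(D)) / den
    return pi


def naive_smoothing_factor(z, h_norm, window, beta, grid_shape):
    H, W = grid_shape
    C = z.shape[1]
    G = np.zeros_like(z)
    for j in range(C):
        field = (z[:, j] + h_norm[:, j]).reshape(H, W)
        G[:, j] = np.exp(beta / (2.0 * window * window)
                         * naive_box_sum(field, window)).ravel()
    return G


def naive_combined_prior(z, G):
    N, C = z.shape
    pi = np.zeros_like(z)
    for i in range(N):
        den = sum(z[i, k] + G[i, k] for k in range(C))
        for j in range(C):
            pi[i, j] = (z[i, j] + G[i, j]) / den
    return pi


# ---------------------------------------------------------------------------
# Moment updates, explicit loops
# ---------------------------------------------------------------------------

def naive_class_moments(X, z, s):
    N, C = z.shape
    D = X.shape[1]
    mu = np.zeros((C, D))
    sigma2 = np.zeros((C, D))
    for j in range(C):
        for l in range(D):
            M = sum(z[i, j] * s[i, j, l] for i in range(N))
            mu[j, l] = sum(z[i, j] * s[i, j, l] * X[i, l]
                           for i in range(N)) / M
            sigma2[j, l] = sum(z[i, j] * s[i, j, l]
                               * (X[i, l] - mu[j, l]) ** 2
                               for i in range(N)) / M
    return mu, sigma2


def naive_background_moments(X, z, s):
    N, C = z.shape
    D = X.shape[1]
    eps = np.zeros(D)
    nu2 = np.zeros(D)
    for l in range(D):
        F = sum(z[i, j] * (1 - s[i, j, l])
                for i in range(N) for j in range(C))
        eps[l] = sum(z[i, j] * (1 - s[i, j, l]) * X[i, l]
                     for i in range(N) for j in range(C)) / F
        nu2[l] = sum(z[i, j] * (1 - s[i, j, l]) * (X[i, l] - eps[l]) ** 2
                     for i in range(N) for j in range(C)) / F
    return eps, nu2


def naive_saliency_prior(z, s):
    N, C = z.shape
    D = s.shape[2]
    return np.array([
        sum(z[i, j] * s[i, j, l] for i in range(N) for j in range(C)) / N
        for l in range(D)])


# ---------------------------------------------------------------------------
# Grid-search minimisers of the objective restricted to one coordinate
# ---------------------------------------------------------------------------

def grid_min_saliency(x, mu, sig2, eps, nu2, rho, gamma, step=1e-4):
    """Minimise the s-dependent objective terms for one (i, j, l) triple."""
    lc = math.log(1 / math.sqrt(2 * math.pi * sig2)) - (x - mu) ** 2 / (2 * sig2)
    lb = math.log(1 / math.sqrt(2 * math.pi * nu2)) - (x - eps) ** 2 / (2 * nu2)
    grid = np.arange(step, 1.0, step)
    vals = (-grid * lc - (1 - grid) * lb
            + gamma * (grid * np.log(grid / rho)
                       + (1 - grid) * np.log((1 - grid) / (1 - rho))))
    return grid[int(np.argmin(vals))]


def grid_min_membership(d, K, pi, lam, gamma, step=1e-4):
    """Minimise the one-pixel objective over z in (0,1), C = 2."""
    grid = np.arange(step, 1.0, step)
    vals = (grid * (d[0] + gamma * K[0]) + (1 - grid) * (d[1] + gamma * K[1])
            + lam * (grid * np.log(grid / pi[0])
                     + (1 - grid) * np.log((1 - grid) / pi[1])))
    return grid[int(np.argmin(vals))]


def bruteforce_mcr(pred, true):
    """MCR by exhaustive enumeration of all label permutations (C <= 4)."""
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    C = int(max(pred.max(), true.max())) + 1
    best = 0
    for perm in itertools.permutations(range(C)):
        mapped = np.array(perm)[pred]
        best = max(best, int((mapped == true).sum()))
    return 100.0 * (1.0 - best / pred.size)


# ---------------------------------------------------------------------------
# Random valid problem instances
# ---------------------------------------------------------------------------

def random_instance(rng, H=4, W=5, C=3, D=2):
    """A random feature matrix, parameter set and membership state."""
    N = H * W
    features = PixelFeatureMatrix(rng.uniform(0, 255, size=(N, D)), (H, W))
    params = ClusterParameters(
        mu=rng.uniform(20, 235, size=(C, D)),
        sigma2=rng.uniform(25, 900, size=(C, D)),
        eps=rng.uniform(60, 200, size=D),
        nu2=rng.uniform(100, 3000, size=D),
        rho=rng.uniform(0.2, 0.8, size=D),
    )
    z = rng.uniform(0.05, 1.0, size=(N, C))
    z /= z.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.05, 1.0, size=(N, C))
    pi /= pi.sum(axis=1, keepdims=True)
    state = MembershipState(
        z=z,
        s=rng.uniform(0.05, 0.95, size=(N, C, D)),
        pi=pi,
        G=rng.uniform(1.0, math.e, size=(N, C)),
    )
    return features, params, state
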