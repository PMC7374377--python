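"""Algorithm configuration shared by the library, the estimators and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class AlgorithmConfig:
    """Tunable parameters of the neighbourhood-constrained saliency clustering.

    Parameters
    ----------
    n_clusters : int
        Number of classes C (>= 2 for segmentation).
    window : int
        Odd side length of the square neighbourhood window (3, 5 or 7).
        The neighbourhood size N_i is ``window**2`` including the centre.
    lam : float
        Regularisation weight of the KL membership penalty tying the
        memberships to the spatial prior. Larger values trust the prior more.
    gamma : float
        Feature-saliency tempering parameter; controls how sharply the
        saliency posterior responds to the class/background likelihood ratio.
    beta : float
        Weight of the noise smoothing factor exponent; G lies in [1, e^beta].
        The default 12 makes the smoothing factor sharply class-discriminative
        (the combined prior then concentrates on the locally dominant class);
        small values (< 1) reduce the prior to a nearly uniform field and the
        memberships stay maximally fuzzy.
    alpha : float
        Exponent applied to the windowed class-likelihood sum when building
        the neighbourhood weights.
    delta : float
        Convergence threshold on the absolute objective decrease.
    max_iter : int
        Maximum number of outer iterations.
    seed : int
        Seed driving the fuzzy C-means centre initialisation (the only
        stochastic step of the solver).
    variance_floor : float
        Lower bound on every class and background variance (grey-level^2).
    rho_floor : float
        Saliency priors are clipped to [rho_floor, 1 - rho_floor].
    fcm_fuzzifier : float
        Fuzzifier m > 1 of the initialising fuzzy C-means run.
    features : str
        Per-pixel feature construction: "intensity" (D = 1, raw grey level)
        or "intensity_mean" (D = 2, grey level plus 3x3 window mean).
    """

    n_clusters: int = 2
    window: int = 5
    lam: float = 150.0
    gamma: float = 15.0
    beta: float = 12.0
    alpha: float = 2.0
    delta: float = 1e-4
    max_iter: int = 400
    seed: int = 0
    variance_floor: float = 1e-4
    rho_floor: float = 1e-3
    fcm_fuzzifier: float = 2.0
    features: str = "intensity"

    def validate(self) -> "AlgorithmConfig":
        if self.n_clusters < 2:
            raise ValueError(f"n_clusters must be >= 2, got {self.n_clusters}")
        if self.window not in (3, 5, 7):
            raise ValueError(f"window must be one of 3, 5, 7, got {self.window}")
        for name in ("lam", "gamma", "beta", "alpha", "delta", "variance_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.rho_floor < 0.5:
            raise ValueError("rho_floor must lie in (0, 0.5)")
        if self.fcm_fuzzifier <= 1:
            raise ValueError("fcm_fuzzifier must be > 1")
        if self.features not in ("intensity", "intensity_mean"):
            raise ValueError(f"unknown feature mode {self.features!r}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AlgorithmConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AlgorithmConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
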