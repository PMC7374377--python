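"""Phantom images and noise simulators.

Piecewise-constant multi-region phantoms (2-4 grey-level classes) stand in
for the synthetic man-made-object and composite test scenes used to study
noise-robust segmentation; the corruption models are additive Gaussian
noise, salt-and-pepper impulse noise, multiplicative (speckle) noise, and
Gaussian + salt-and-pepper mixtures. Every generator is a pure function of
its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NOISE_KINDS = ("gaussian", "salt_pepper", "multiplicative", "mixed")
PHANTOM_KINDS = ("two_region", "four_region", "stripes")


@dataclass(frozen=True)
class NoiseSpec:
    """Declarative description of a corruption process.

    ``gaussian_std`` and the speckle level are expressed on the 0-255 grey
    scale; speckle is applied as I + I*n with n ~ Normal(0, (std/255)^2).
    ``sp_fraction`` is the expected proportion of impulse-corrupted pixels.
    """

    kind: str
    gaussian_mean: float = 0.0
    gaussian_std: float = 0.0
    sp_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; "
                             f"expected one of {NOISE_KINDS}")
        if not 0.0 <= self.sp_fraction <= 0.9:
            raise ValueError("sp_fraction must lie in [0, 0.9]")
        if self.gaussian_std < 0:
            raise ValueError("gaussian_std must be non-negative")


@dataclass(frozen=True)
class Phantom:
    """A clean piecewise-constant image with its ground-truth label map."""

    clean: np.ndarray   # (H, W) uint8
    truth: np.ndarray   # (H, W) int labels
    levels: tuple[int, ...]


def make_phantom(kind: str, H: int = 128, W: int = 128,
                 levels=(60, 180), seed: int = 0) -> Phantom:
    """Deterministic geometric phantom layouts.

    two_region: centred disk (label 1) on background (label 0); 2 levels.
    four_region: quadrant blocks, each carrying an inset rectangle of the
    diagonally opposite class, so all four classes appear in several
    places; 4 levels. stripes: equal vertical bands; 2-4 levels.
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}")
    if H < 32 or W < 32:
        raise ValueError("phantom must be at least 32x32")
    levels = tuple(int(v) for v in levels)
    if len(set(levels)) != len(levels):
        raise ValueError(f"grey levels must be distinct, got {levels}")
    if not all(0 <= v <= 255 for v in levels):
        raise ValueError("grey levels must lie in [0, 255]")

    if kind == "two_region":
        if len(levels) != 2:
            raise ValueError("two_region needs exactly 2 levels")
        rr, cc = np.mgrid[0:H, 0:W]
        radius = min(H, W) / 4.0
        truth = (((rr - (H - 1) / 2.0) ** 2 + (cc - (W - 1) / 2.0) ** 2)
                 <= radius ** 2).astype(int)
    elif kind == "four_region":
        if len(levels) != 4:
            raise ValueError("four_region needs exactly 4 levels")
        truth = np.zeros((H, W), dtype=int)
        h2, w2 = H // 2, W // 2
        quads = {0: (0, h2, 0, w2), 1: (0, h2, w2, W),
                 2: (h2, H, 0, w2), 3: (h2, H, w2, W)}
        for q, (r0, r1, c0, c1) in quads.items():
            truth[r0:r1, c0:c1] = q
            # inset rectangle of the diagonally opposite class
            ih, iw = (r1 - r0) // 3, (c1 - c0) // 3
            rm, cm = (r0 + r1) // 2, (c0 + c1) // 2
            truth[rm - ih // 2: rm + (ih + 1) // 2,
                  cm - iw // 2: cm + (iw + 1) // 2] = 3 - q
    else:  # stripes
        if not 2 <= len(levels) <= 4:
            raise ValueError("stripes needs 2-4 levels")
        k = len(levels)
        truth = np.minimum((np.arange(W) * k) // W, k - 1)
        truth = np.broadcast_to(truth, (H, W)).astype(int).copy()

    clean = np.asarray(levels, dtype=np.uint8)[truth]
    return Phantom(clean=clean, truth=truth, levels=levels)


def corrupt(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Apply the corruption described by ``spec`` to an 8-bit image.

    Outputs are clipped to [0, 255] and rounded back to uint8; the mixed
    kind applies Gaussian then salt-and-pepper noise using independent
    substreams of the same seed.
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError(f"expected a uint8 image, got dtype {img.dtype}")
    if spec.kind == "mixed":
        g_ss, sp_ss = np.random.SeedSequence(spec.seed).spawn(2)
        out = _add_gaussian(img.astype(float), spec,
                            np.random.default_rng(g_ss))
        out = _add_salt_pepper(out, spec.sp_fraction,
                               np.random.default_rng(sp_ss))
    else:
        rng = np.random.default_rng(spec.seed)
        x = img.astype(float)
        if spec.kind == "gaussian":
            out = _add_gaussian(x, spec, rng)
        elif spec.kind == "salt_pepper":
            out = _add_salt_pepper(x, spec.sp_fraction, rng)
        else:  # multiplicative
            n = rng.normal(0.0, spec.gaussian_std / 255.0, size=x.shape)
            out = x + x * n
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _add_gaussian(x: np.ndarray, spec: NoiseSpec,
                  rng: np.random.Generator) -> np.ndarray:
    return x + rng.normal(spec.gaussian_mean, spec.gaussian_std, size=x.shape)


def _add_salt_pepper(x: np.ndarray, fraction: float,
                     rng: np.random.Generator) -> np.ndarray:
    mask = rng.random(x.shape) < fraction
    values = np.where(rng.random(x.shape) < 0.5, 0.0, 255.0)
    return np.where(mask, values, x)
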