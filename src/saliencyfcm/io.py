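"""Image and result I/O.

Label maps are stored as plain 8-bit PNGs holding the integer class index
per pixel (lossless round-trip); the class-mean reconstruction replaces
every pixel by the converged intensity mean of its class.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .config import AlgorithmConfig
from .model import SegmentationResult


@dataclass
class RunManifest:
    config: dict
    seed: int
    inputs: list[str]
    outputs: list[str]
    iterations: int
    converged: bool
    wall_time_s: float

    def to_dict(self) -> dict:
        return {
            "config": self.config, "seed": self.seed, "inputs": self.inputs,
            "outputs": self.outputs, "iterations": self.iterations,
            "converged": self.converged, "wall_time_s": self.wall_time_s,
        }


def read_grey_image(path: str | Path) -> np.ndarray:
    """Read a single-channel 8-bit PNG/TIFF image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = iio.imread(path)
    if img.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel greyscale image, got "
            f"shape {img.shape} (multi-channel input is not supported)")
    if img.dtype != np.uint8:
        bits = img.dtype.itemsize * 8
        raise ValueError(f"{path}: expected 8-bit data, got {bits}-bit "
                         f"({img.dtype})")
    return img


def write_grey_image(path: str | Path, image: np.ndarray) -> None:
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError(f"refusing to write non-uint8 image ({arr.dtype})")
    iio.imwrite(Path(path), arr)


def write_outputs(result: SegmentationResult, out_dir: str | Path,
                  config: AlgorithmConfig | None = None,
                  inputs: list[str] | None = None,
                  started_at: float | None = None) -> RunManifest:
    """Write label map, class-mean reconstruction and JSON sidecar.

    Returns the run manifest (also written to ``manifest.json``). The
    sidecar ``result.json`` is fully determined by the segmentation, so
    identical runs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = result.labels.astype(np.uint8)
    recon = np.clip(np.rint(result.params.mu[:, 0]), 0, 255).astype(np.uint8)
    recon_img = recon[result.labels]

    labels_path = out / "labels.png"
    recon_path = out / "reconstruction.png"
    sidecar_path = out / "result.json"
    write_grey_image(labels_path, labels)
    write_grey_image(recon_path, recon_img)

    sidecar = {
        "config": config.to_dict() if config is not None else None,
        "iterations": result.iterations,
        "converged": result.converged,
        "objective_trace": [float(v) for v in result.objective_trace],
        "params": {
            "mu": result.params.mu.tolist(),
            "sigma2": result.params.sigma2.tolist(),
            "eps": result.params.eps.tolist(),
            "nu2": result.params.nu2.tolist(),
            "rho": result.params.rho.tolist(),
        },
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    manifest = RunManifest(
        config=config.to_dict() if config is not None else {},
        seed=config.seed if config is not None else 0,
        inputs=list(inputs or []),
        outputs=[str(labels_path), str(recon_path), str(sidecar_path)],
        iterations=result.iterations,
        converged=result.converged,
        wall_time_s=(time.monotonic() - started_at) if started_at else 0.0,
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True))
    return manifest
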