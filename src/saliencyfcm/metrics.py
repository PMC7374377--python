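"""Segmentation quality metrics: PSNR and misclassification rate.

Cluster labels are arbitrary, so the misclassification rate first aligns
predicted and true labels by solving the assignment problem that maximises
the matched pixel count (Hungarian algorithm on the confusion matrix).
PSNR compares two grey-level renderings of segmentations:
PSNR = 10 log10(MAX^2 / MSE) with MAX = 255 for 8-bit material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class EvaluationReport:
    psnr_db: float
    mse: float
    mcr_percent: float
    label_mapping: list[int]
    confusion: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "psnr_db": self.psnr_db,
            "mse": self.mse,
            "mcr_percent": self.mcr_percent,
            "label_mapping": list(self.label_mapping),
            "confusion": np.asarray(self.confusion).tolist(),
        }


def psnr(result_image: np.ndarray, reference_image: np.ndarray,
         max_level: float = 255.0) -> tuple[float, float]:
    """Pixelwise mean squared error and peak signal-to-noise ratio.

    Returns ``(mse, psnr_db)``; identical images report ``psnr_db = inf``.
    """
    a = np.asarray(result_image, dtype=float)
    b = np.asarray(reference_image, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return 0.0, float("inf")
    return mse, float(10.0 * np.log10(max_level ** 2 / mse))


def mcr(pred_labels: np.ndarray, true_labels: np.ndarray):
    """Misclassification rate (%) after optimal label alignment.

    Returns ``(mcr_percent, mapping, confusion)`` where ``mapping[p]`` is
    the true label assigned to predicted label ``p`` and ``confusion`` is
    the C x C matrix of (predicted, true) pixel counts.
    """
    pred = np.asarray(pred_labels).ravel()
    true = np.asarray(true_labels).ravel()
    if pred.size == 0:
        raise ValueError("empty label maps")
    if pred.shape != true.shape:
        raise ValueError("label maps differ in size")
    if pred.min() < 0 or true.min() < 0:
        raise ValueError("labels must be non-negative integers")
    C = int(max(pred.max(), true.max())) + 1
    confusion = np.zeros((C, C), dtype=np.int64)
    np.add.at(confusion, (pred, true), 1)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    mapping = np.empty(C, dtype=int)
    mapping[rows] = cols
    matched = confusion[rows, cols].sum()
    rate = 100.0 * (1.0 - matched / pred.size)
    return float(rate), mapping, confusion


def render_labels(labels: np.ndarray, levels) -> np.ndarray:
    """Render a label map with fixed grey levels per class (uint8)."""
    levels = np.asarray(levels, dtype=np.uint8)
    return levels[np.asarray(labels)]


def class_mean_image(labels: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Replace each pixel by the mean of ``source`` over its class (float)."""
    labels = np.asarray(labels)
    src = np.asarray(source, dtype=float)
    if labels.shape != src.shape:
        raise ValueError("labels and source image differ in shape")
    out = np.empty_like(src)
    for lab in np.unique(labels):
        m = labels == lab
        out[m] = src[m].mean()
    return out


def evaluate_segmentation(pred_labels: np.ndarray, true_labels: np.ndarray,
                          levels=None, pred_recon: np.ndarray | None = None,
                          ref_recon: np.ndarray | None = None) -> EvaluationReport:
    """MCR plus PSNR in one report.

    PSNR operands are either the supplied reconstructions or, when
    ``levels`` is given, both label maps rendered with those grey levels
    after aligning predicted labels to the truth.
    """
    rate, mapping, confusion = mcr(pred_labels, true_labels)
    if pred_recon is not None and ref_recon is not None:
        mse, db = psnr(pred_recon, ref_recon)
    elif levels is not None:
        aligned = mapping[np.asarray(pred_labels)]
        mse, db = psnr(render_labels(aligned, levels),
                       render_labels(true_labels, levels))
    else:
        mse, db = float("nan"), float("nan")
    return EvaluationReport(psnr_db=db, mse=mse, mcr_percent=rate,
                            label_mapping=list(map(int, mapping)),
                            confusion=confusion)
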