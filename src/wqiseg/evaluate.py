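"""Quantitative evaluation: fidelity (MSE/PSNR), pixel-level detection
quality (confusion counts, ROC, precision) and mask overlap (IoU)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "mse_psnr", "confusion", "roc_curve", "precision", "iou"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def mse_psnr(original: np.ndarray, filtered: np.ndarray) -> tuple[float, float]:
    """Mean squared error and ``PSNR = 20·log10(255/sqrt(MSE))`` in dB.

    Identical images give MSE 0 and an infinite PSNR.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(filtered, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return 0.0, float("inf")
    return mse, 20.0 * np.log10(255.0 / np.sqrt(mse))


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts of a predicted mask against ground truth."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must share a shape")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def roc_curve(
    score: np.ndarray, truth: np.ndarray, thresholds=None
) -> list[tuple[float, float]]:
    """ROC points (FPR, TPR) for ``score > threshold`` detectors.

    Standard rates: TPR = TP/(TP+FN), FPR = FP/(FP+TN). Thresholds must be
    sorted ascending; the trivial endpoints (0,0) and (1,1) are appended. A
    degenerate truth (all foreground or all background) yields NaN sentinels
    with a warning.
    """
    score = np.asarray(score, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if score.shape != truth.shape:
        raise ValueError("score and truth must share a shape")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("degenerate ground truth: ROC rates undefined")
        return [(float("nan"), float("nan"))]
    if thresholds is None:
        thresholds = np.quantile(score, np.linspace(0.0, 1.0, 64))
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    pts = [(0.0, 0.0)]
    for th in thresholds[::-1]:  # descending threshold -> increasing rates
        pred = score > th
        c = confusion(pred, truth)
        pts.append((c.fp / n_neg, c.tp / n_pos))
    pts.append((1.0, 1.0))
    return pts


def precision(counts: ConfusionCounts) -> float:
    """``TP / (TP + FP)``; with no positive predictions defined as 1.0."""
    denom = counts.tp + counts.fp
    if denom == 0:
        warnings.warn("no positive predictions: precision defined as 1.0")
        return 1.0
    return counts.tp / denom


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two masks; two empty masks agree (1.0)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must share a shape")
    union = int(np.sum(pred | truth))
    if union == 0:
        return 1.0
    return int(np.sum(pred & truth)) / union
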