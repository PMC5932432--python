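"""Evaluation of gray-scale detections (ROC area) and binary masks (accuracy).

The detection response is a gray-scale vessel-likelihood map; sweeping a
threshold over it and tabulating the true-positive fraction (TPF,
sensitivity) against the false-positive fraction (FPF) at each cutoff traces
the ROC curve, whose area A_z summarizes ranking quality (1.0 = perfect,
0.5 = uninformative).  Binary segmentations are scored by pixel accuracy,
(TP + TN) / (TP + FP + TN + FN), with vessel as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "RocCurve", "confusion", "accuracy", "roc", "auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tabulation of a predicted mask against ground truth (vessel = positive)."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class RocCurve:
    """Ordered (FPF, TPF) pairs from a threshold sweep, including (0,0) and (1,1)."""

    points: np.ndarray
    thresholds: np.ndarray

    @property
    def fpf(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpf(self) -> np.ndarray:
        return self.points[:, 1]


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} must be binary, found values {vals[:5]}")
        mask = mask.astype(bool)
    return mask


def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """2x2 pixel tabulation of a binary prediction against binary ground truth."""
    pred = _as_binary(pred_mask, "pred_mask")
    gt = _as_binary(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return ConfusionCounts(
        TP=int(np.sum(pred & gt)),
        FP=int(np.sum(pred & ~gt)),
        TN=int(np.sum(~pred & ~gt)),
        FN=int(np.sum(~pred & gt)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correctly classified pixels, (TP + TN) / total."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.TP + c.TN) / c.total


def roc(response: np.ndarray, gt_mask: np.ndarray, n_thresholds: int = 256) -> RocCurve:
    """ROC curve of a gray-scale response against a binary ground truth.

    Sweeps ``n_thresholds + 1`` evenly spaced cutoffs over the response range
    (predicted positive = response >= cutoff, swept from high to low so FPF
    and TPF are non-decreasing) and appends the (0, 0) and (1, 1) endpoints.
    ``response`` and ``gt_mask`` may have any common shape.
    """
    response = np.asarray(response, dtype=np.float64)
    gt = _as_binary(gt_mask, "gt_mask")
    if response.shape != gt.shape:
        raise ValueError(f"shape mismatch: {response.shape} vs {gt.shape}")
    gt = gt.ravel()
    scores = response.ravel()
    n_pos = int(gt.sum())
    n_neg = gt.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ground truth must contain both classes")
    lo, hi = float(scores.min()), float(scores.max())
    cutoffs = np.linspace(hi, lo, n_thresholds + 1)  # descending
    pos_sorted = np.sort(scores[gt])
    neg_sorted = np.sort(scores[~gt])
    tpf = (n_pos - np.searchsorted(pos_sorted, cutoffs, side="left")) / n_pos
    fpf = (n_neg - np.searchsorted(neg_sorted, cutoffs, side="left")) / n_neg
    points = np.column_stack([fpf, tpf])
    points = np.vstack([[0.0, 0.0], points, [1.0, 1.0]])
    thresholds = np.concatenate([[np.inf], cutoffs, [-np.inf]])
    return RocCurve(points=points, thresholds=thresholds)


def auc(curve: RocCurve, rule: str = "trapezoid") -> float:
    """Area under the ROC curve by a Riemann-type sum over FPF-sorted points.

    ``rule`` is ``"trapezoid"`` (default) or ``"left"`` for the literal
    left-endpoint Riemann sum (which biases the area low).
    """
    pts = curve.points
    if len(pts) < 2:
        raise ValueError("need at least two ROC points")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    fpf, tpf = pts[order, 0], pts[order, 1]
    if rule == "trapezoid":
        return float(np.trapezoid(tpf, fpf))
    if rule == "left":
        return float(np.sum(tpf[:-1] * np.diff(fpf)))
    raise ValueError(f"unknown rule {rule!r}")
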