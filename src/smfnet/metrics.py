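"""Evaluation metrics on hard label maps: Dice, mean IoU, 95th-percentile
Hausdorff distance on boundaries, and pixel-level mean absolute error on
probability maps.

Conventions: classes empty in both prediction and truth are excluded from
class means; HD95 uses 4-connectivity boundary pixels, Euclidean distances
in pixel units, and the linear-interpolation percentile of the pooled
directed distances; an empty boundary on either side yields NaN (undefined),
never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class MetricReport:
    """Per-sample or aggregated segmentation quality summary."""

    dice_per_class: dict[int, float] = field(default_factory=dict)
    mean_dice: float = float("nan")
    miou: float = float("nan")
    hd95: float = float("nan")
    mae: float = float("nan")

    def to_dict(self) -> dict:
        return {"dice_per_class": {str(k): v for k, v in self.dice_per_class.items()},
                "mean_dice": self.mean_dice, "miou": self.miou,
                "hd95": self.hd95, "mae": self.mae}


def dice_metric(pred: np.ndarray, truth: np.ndarray,
                classes: tuple[int, ...]) -> dict[int, float]:
    """Per-class Dice 2|P∩Y|/(|P|+|Y|); both-empty classes are omitted."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    out: dict[int, float] = {}
    for c in classes:
        p = pred == c
        y = truth == c
        denom = p.sum() + y.sum()
        if denom == 0:
            continue
        out[c] = 2.0 * np.logical_and(p, y).sum() / denom
    return out


def miou_metric(pred: np.ndarray, truth: np.ndarray,
                classes: tuple[int, ...]) -> float:
    """Mean over classes of |P∩Y|/|P∪Y|."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    ious = []
    for c in classes:
        p = pred == c
        y = truth == c
        union = np.logical_or(p, y).sum()
        if union == 0:
            continue
        ious.append(np.logical_and(p, y).sum() / union)
    return float(np.mean(ious)) if ious else float("nan")


def _boundary(mask: np.ndarray) -> np.ndarray:
    """4-connectivity boundary: mask minus its erosion."""
    if not mask.any():
        return mask
    return mask & ~ndimage.binary_erosion(mask, structure=_CROSS,
                                          border_value=0)


def hd95(pred: np.ndarray, truth: np.ndarray, cls: int) -> float:
    """95th percentile of pooled directed boundary distances (pixel units).

    Returns NaN when either class region has no boundary pixels.
    """
    a = _boundary(pred == cls)
    b = _boundary(truth == cls)
    if not a.any() or not b.any():
        return float("nan")
    # distance_transform_edt gives, at every pixel, the distance to the
    # nearest zero of the input; feed it the complement of each boundary.
    dist_to_b = ndimage.distance_transform_edt(~b)
    dist_to_a = ndimage.distance_transform_edt(~a)
    pooled = np.concatenate([dist_to_b[a], dist_to_a[b]])
    return float(np.percentile(pooled, 95))


def mae_metric(probs: np.ndarray, truth: np.ndarray) -> float:
    """Mean |p - y| over all pixels and classes (one-vs-rest one-hot truth)."""
    k = probs.shape[0] if probs.ndim == 3 else probs.shape[1]
    if probs.ndim == 3:
        probs = probs[None]
        truth = truth[None]
    oh = np.stack([(truth == c).astype(probs.dtype) for c in range(k)], axis=1)
    return float(np.abs(probs - oh).mean())


def evaluate_sample(pred_labels: np.ndarray, truth: np.ndarray,
                    probs: np.ndarray | None = None,
                    foreground: tuple[int, ...] = (1, 2)) -> MetricReport:
    """Full report on one label map (foreground classes only in the means)."""
    d = dice_metric(pred_labels, truth, foreground)
    hs = [hd95(pred_labels, truth, c) for c in foreground]
    hs = [h for h in hs if not np.isnan(h)]
    return MetricReport(
        dice_per_class=d,
        mean_dice=float(np.mean(list(d.values()))) if d else float("nan"),
        miou=miou_metric(pred_labels, truth, foreground),
        hd95=float(np.mean(hs)) if hs else float("nan"),
        mae=mae_metric(probs, truth) if probs is not None else float("nan"))


def mean_reports(reports: list[MetricReport]) -> MetricReport:
    """NaN-aware average of per-sample reports."""
    def nanmean(vals):
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    classes = sorted({c for r in reports for c in r.dice_per_class})
    per_class = {c: nanmean([r.dice_per_class[c] for r in reports
                             if c in r.dice_per_class]) for c in classes}
    return MetricReport(
        dice_per_class=per_class,
        mean_dice=nanmean([r.mean_dice for r in reports]),
        miou=nanmean([r.miou for r in reports]),
        hd95=nanmean([r.hd95 for r in reports]),
        mae=nanmean([r.mae for r in reports]))
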