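"""Pixel-level segmentation metrics: confusion counts, IoU and Dice.

IoU = TP / (TP + FP + FN) and Dice = 2 TP / (FP + 2 TP + FN) over pixel
counts.  Both are defined as 1 when prediction and reference are both empty
(the 0/0 case), and they satisfy the identity Dice = 2 IoU / (1 + IoU).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import ShapeError

__all__ = ["SegMetrics", "confusion_counts", "iou", "dice", "evaluate_arrays"]


def confusion_counts(pred: np.ndarray, label: np.ndarray) -> tuple[int, int, int, int]:
    """Pixel-wise (TP, FP, FN, TN) between two binary masks."""
    pred = np.asarray(pred)
    label = np.asarray(label)
    if pred.shape != label.shape:
        raise ShapeError(f"pred shape {pred.shape} != label shape {label.shape}")
    for name, a in (("pred", pred), ("label", label)):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    p = pred.astype(bool)
    y = label.astype(bool)
    tp = int(np.count_nonzero(p & y))
    fp = int(np.count_nonzero(p & ~y))
    fn = int(np.count_nonzero(~p & y))
    tn = int(np.count_nonzero(~p & ~y))
    return tp, fp, fn, tn


def _check_counts(*counts):
    for c in counts:
        if c < 0:
            raise ValueError(f"negative pixel count {c}")


def iou(tp: int, fp: int, fn: int) -> float:
    """Intersection over union; 1.0 for the empty-vs-empty case."""
    _check_counts(tp, fp, fn)
    denom = tp + fp + fn
    if denom == 0:
        return 1.0
    return tp / denom


def dice(tp: int, fp: int, fn: int) -> float:
    """Dice similarity coefficient; 1.0 for the empty-vs-empty case."""
    _check_counts(tp, fp, fn)
    denom = fp + 2 * tp + fn
    if denom == 0:
        return 1.0
    return 2 * tp / denom


@dataclass(frozen=True)
class SegMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def iou(self) -> float:
        return iou(self.tp, self.fp, self.fn)

    @property
    def dice(self) -> float:
        return dice(self.tp, self.fp, self.fn)

    @property
    def total_pixels(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "SegMetrics") -> "SegMetrics":
        return SegMetrics(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn, self.tn + other.tn)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "iou": self.iou, "dice": self.dice}


def evaluate_arrays(pred_masks: np.ndarray, labels: np.ndarray,
                    average: str = "micro") -> dict:
    """Aggregate Dice/IoU over a stack of binary masks.

    micro: pool pixel counts over all images then compute the metrics once;
    macro: average per-image metrics.  Returns both the pooled counts and the
    requested averages.
    """
    if average not in ("micro", "macro"):
        raise ValueError(f"average must be 'micro' or 'macro', got {average!r}")
    if len(pred_masks) == 0:
        raise ValueError("empty dataset")
    per_image = [SegMetrics(*confusion_counts(p, y))
                 for p, y in zip(pred_masks, labels)]
    pooled = per_image[0]
    for m in per_image[1:]:
        pooled = pooled + m
    out = {"counts": pooled, "micro_dice": pooled.dice, "micro_iou": pooled.iou,
           "macro_dice": float(np.mean([m.dice for m in per_image])),
           "macro_iou": float(np.mean([m.iou for m in per_image]))}
    out["dice"] = out[f"{average}_dice"]
    out["iou"] = out[f"{average}_iou"]
    return out
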