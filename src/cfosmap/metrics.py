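"""Voxel-wise segmentation evaluation: confusion counts, Dice, sensitivity, Jaccard."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import MaskVolume

__all__ = ["ConfusionCounts", "confusion", "dice", "sensitivity", "jaccard", "evaluate"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-level confusion between a predicted and a ground-truth mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def both_empty(self) -> bool:
        """Neither mask has a positive voxel; overlap metrics are 1.0 by convention."""
        return self.tp + self.fp + self.fn == 0


def _as_bool(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, MaskVolume) else np.asarray(mask)
    return data.astype(bool)


def confusion(pred, gt) -> ConfusionCounts:
    """Exact voxel counts of TP/FP/FN/TN between two same-shape binary masks."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice(c: ConfusionCounts) -> float:
    """Dice = 2TP / (2TP + FP + FN); 1.0 when both masks are empty."""
    if c.both_empty:
        return 1.0
    return 2 * c.tp / (2 * c.tp + c.fp + c.fn)


def sensitivity(c: ConfusionCounts) -> float:
    """Sensitivity (recall) = TP / (TP + FN); 1.0 when ground truth is empty."""
    if c.tp + c.fn == 0:
        return 1.0
    return c.tp / (c.tp + c.fn)


def jaccard(c: ConfusionCounts) -> float:
    """Jaccard = TP / (TP + FP + FN); 1.0 when both masks are empty."""
    if c.both_empty:
        return 1.0
    return c.tp / (c.tp + c.fp + c.fn)


def evaluate(pred, gt) -> dict:
    """All three metrics at once, with the empty-vs-empty convention flagged."""
    c = confusion(pred, gt)
    return {
        "dice": dice(c),
        "sensitivity": sensitivity(c),
        "jaccard": jaccard(c),
        "both_empty": c.both_empty,
    }
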