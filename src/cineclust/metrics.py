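"""Segmentation, detection and temporal evaluation metrics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from cineclust import flow as _flow


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_masks(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        pred = _as_binary(pred)
        truth = _as_binary(truth)
        if pred.shape != truth.shape:
            raise ValueError("mask shapes differ")
        return cls(tp=int(np.sum(pred & truth)), fp=int(np.sum(pred & ~truth)),
                   fn=int(np.sum(~pred & truth)), tn=int(np.sum(~pred & ~truth)))


def _as_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return mask
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary (values 0/1 or bool)")
    return mask.astype(bool)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity 2|A&B| / (|A|+|B|); two empty masks score 1."""
    a = _as_binary(pred)
    b = _as_binary(truth)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * float(np.sum(a & b)) / denom


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard index |A&B| / |A|B|; two empty masks score 1."""
    a = _as_binary(pred)
    b = _as_binary(truth)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return float(np.sum(a & b)) / union


def detection_scores(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity (%), precision, F1 and accuracy (%) from confusion counts.

    Undefined ratios (zero denominators) come back as NaN with a warning.
    """
    out: dict[str, float] = {}

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return float("nan")
        return num / den

    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    prec = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    out["sensitivity"] = 100.0 * sens if np.isfinite(sens) else sens
    out["precision"] = prec
    if np.isfinite(sens) and np.isfinite(prec) and (sens + prec) > 0:
        out["f1"] = 2.0 * prec * sens / (prec + sens)
    elif sens == 0 and prec == 0:
        out["f1"] = 0.0
    else:
        warnings.warn("f1 undefined")
        out["f1"] = float("nan")
    acc = _ratio(counts.tp + counts.tn, counts.n, "accuracy")
    out["accuracy"] = 100.0 * acc if np.isfinite(acc) else acc
    return out


def temporal_consistency(masks: np.ndarray, flowfield: "_flow.FlowField",
                         threshold: float = 0.5,
                         nearest: bool = False) -> float:
    """Motion-compensated overlap of a mask sequence, in [0, 1].

    Each mask_t is warped onto the grid of frame t+1 with the flow of that
    pair (bilinear by default, then thresholded; ``nearest`` switches to
    nearest-neighbour sampling) and compared to mask_{t+1} with Dice; the
    mean over consecutive pairs is returned.  A sequence segmented
    consistently with its own motion scores near 1.
    """
    masks = _as_binary(masks)
    if masks.ndim != 3 or masks.shape[0] < 2:
        raise ValueError("masks must be (T, H, W) with T >= 2")
    vec = flowfield.vectors
    if vec.shape[0] != masks.shape[0] - 1 or vec.shape[1:3] != masks.shape[1:]:
        raise ValueError("flow field does not match mask sequence")
    if not masks.any():
        warnings.warn("all masks empty; temporal consistency = 1 by convention")
        return 1.0
    scores = []
    for t in range(masks.shape[0] - 1):
        m = masks[t].astype(np.float64)
        if nearest:
            H, W = m.shape
            rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
            sr = np.clip(np.round(rr + vec[t, ..., 0]).astype(int), 0, H - 1)
            sc = np.clip(np.round(cc + vec[t, ..., 1]).astype(int), 0, W - 1)
            warped = m[sr, sc]
        else:
            warped = _flow.warp(m, vec[t])
        scores.append(dice(warped >= threshold, masks[t + 1]))
    return float(np.mean(scores))


def partition_concordance(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Optimal-matching overlap between two label partitions, in [0, 1].

    Clusters of the two maps are matched one-to-one by solving the
    assignment problem on the contingency table (maximizing summed overlap);
    the score is matched overlap over the total pixel count.  Invariant to
    label permutations; noise pixels (-1) in either map are excluded.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("label maps must share a shape")
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("no non-noise pixels in common support")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((ua.size, ub.size), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    rows, cols = linear_sum_assignment(-table)
    matched = table[rows, cols].sum()
    return float(matched) / a.size
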