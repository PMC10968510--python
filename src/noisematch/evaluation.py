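"""Lesion-level detection scoring.

Predicted and gold lesion components are matched one-to-one with the
Hungarian algorithm maximizing total intersection-over-union (IoU);
matched pairs with IoU > 0 are true positives, remaining predictions
false positives and remaining gold components false negatives.  PPV,
sensitivity and F1 follow the standard count formulas with the 0/0 -> 0
convention, and test-set metrics pool counts over subjects before
forming ratios (lesion-level micro-average).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import LesionMask

__all__ = [
    "MatchRecord",
    "DetectionMetrics",
    "iou",
    "iou_matrix",
    "match_lesions",
    "detection_metrics",
    "evaluate_testset",
]


@dataclass(frozen=True)
class MatchRecord:
    """One matched (prediction, gold) component pair with its IoU."""

    pred_label: int
    gold_label: int
    iou: float


@dataclass(frozen=True)
class DetectionMetrics:
    tp: int
    fp: int
    fn: int
    ppv: float
    sensitivity: float
    f1: float


def iou(component_a: np.ndarray, component_b: np.ndarray) -> float:
    """|A intersect B| / |A union B| of two nonempty voxel sets given as
    boolean masks on the same grid."""
    a = np.asarray(component_a, dtype=bool)
    b = np.asarray(component_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("components must live on the same grid")
    if not a.any() or not b.any():
        raise ValueError("IoU of an empty component is undefined")
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    return inter / union


def iou_matrix(pred: LesionMask, gold: LesionMask) -> np.ndarray:
    """(n_pred, n_gold) matrix of pairwise component IoUs.

    Computed from the joint label histogram in one pass.
    """
    p = np.asarray(pred.labels).ravel()
    g = np.asarray(gold.labels).ravel()
    n_p, n_g = pred.n_components, gold.n_components
    if n_p == 0 or n_g == 0:
        return np.zeros((n_p, n_g))
    joint = np.bincount(p * (n_g + 1) + g, minlength=(n_p + 1) * (n_g + 1))
    joint = joint.reshape(n_p + 1, n_g + 1).astype(float)
    inter = joint[1:, 1:]
    p_sizes = joint[1:, :].sum(axis=1, keepdims=True)
    g_sizes = joint[:, 1:].sum(axis=0, keepdims=True)
    union = p_sizes + g_sizes - inter
    return inter / union


def match_lesions(
    pred: LesionMask, gold: LesionMask
) -> tuple[list[MatchRecord], tuple[int, int, int]]:
    """Hungarian one-to-one matching of predicted vs gold components.

    Returns the matched records (IoU > 0 only) and the (TP, FP, FN)
    counts.  The assignment maximizes total IoU; pairs assigned at
    exactly zero overlap are discarded afterwards.
    """
    if np.asarray(pred.labels).shape != np.asarray(gold.labels).shape:
        raise ValueError("prediction and gold masks are misaligned")
    mat = iou_matrix(pred, gold)
    records: list[MatchRecord] = []
    if mat.size:
        rows, cols = linear_sum_assignment(mat, maximize=True)
        for r, c in zip(rows, cols):
            if mat[r, c] > 0:
                records.append(
                    MatchRecord(
                        pred_label=int(r + 1),
                        gold_label=int(c + 1),
                        iou=float(mat[r, c]),
                    )
                )
    tp = len(records)
    fp = pred.n_components - tp
    fn = gold.n_components - tp
    return records, (tp, fp, fn)


def detection_metrics(tp: int, fp: int, fn: int) -> DetectionMetrics:
    """PPV = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 their harmonic
    mean; any 0/0 ratio is 0 by convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    ppv = tp / (tp + fp) if tp + fp else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
    return DetectionMetrics(tp=tp, fp=fp, fn=fn, ppv=ppv, sensitivity=sens, f1=f1)


def evaluate_testset(model, subjects, profile_name: str | None = None):
    """Pooled detection metrics of a fitted detector over test subjects.

    ``subjects`` is an iterable of phantom ``Subject`` records (or of
    ``(image, gold_mask)`` pairs).  Counts are pooled over all subjects
    before computing the three metrics.  Returns the pooled
    :class:`DetectionMetrics` and a per-subject count table.
    """
    pairs = []
    for s in subjects:
        if isinstance(s, tuple):
            pairs.append(s)
        else:
            name = profile_name or next(iter(s.images))
            pairs.append((s.images[name], s.gold[name]))
    if not pairs:
        raise ValueError("empty test set")
    X = np.stack([img.voxels for img, _ in pairs])
    preds = model.predict(X)
    tp = fp = fn = 0
    per_subject = []
    for (img, gold), pred in zip(pairs, preds):
        _, (t, f, m) = match_lesions(pred, gold)
        per_subject.append(
            {
                "subject_id": getattr(img, "subject_id", ""),
                "tp": t,
                "fp": f,
                "fn": m,
            }
        )
        tp, fp, fn = tp + t, fp + f, fn + m
    return detection_metrics(tp, fp, fn), per_subject
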