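"""Detection-quality metrics for flower/fruit bounding boxes.

Implements the standard object-detection evaluation suite at IoU
threshold 0.5: a prediction whose best IoU against an unclaimed
ground-truth box is >= the threshold is a true positive, otherwise a
false positive; unclaimed ground truths are false negatives.  From the
match counts come precision, recall and F1; ranking predictions by
confidence gives the precision-recall curve, its (monotonized) area is
the per-class average precision (AP), and mAP is the arithmetic mean of
AP over classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from trusscast.boxes import Box, split_by_class

__all__ = [
    "MatchCounts",
    "PRPoint",
    "DetectionReport",
    "iou",
    "match_boxes",
    "precision_recall_f1",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "evaluate_detections",
]


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("match counts must be non-negative")


@dataclass(frozen=True)
class PRPoint:
    """One point of the precision-recall curve at a given score cutoff."""

    precision: float
    recall: float
    threshold: float


@dataclass(frozen=True)
class DetectionReport:
    """Aggregate detection metrics: per-class AP, mAP, F1 and mean IoU."""

    per_class_ap: dict[str, float]
    map_value: float
    precision: float
    recall: float
    f1: float
    avg_iou: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "per_class_ap": self.per_class_ap,
                "mAP": self.map_value,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "avg_iou": self.avg_iou,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    ax0, ay0, ax1, ay1 = a.corners()
    bx0, by0, bx1, by1 = b.corners()
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union


def match_boxes(
    preds: Sequence[Box],
    gts: Sequence[Box],
    iou_thresh: float = 0.5,
) -> tuple[MatchCounts, list[tuple[int, int, float]]]:
    """Match predictions to ground truths greedily by descending IoU.

    Each ground truth claims at most one prediction and vice versa.
    Ties are broken by higher prediction score, then input order.

    Returns
    -------
    counts : MatchCounts
    pairs : list of (pred_index, gt_index, iou) for the true positives.
    """
    if not 0.0 < iou_thresh < 1.0:
        raise ValueError(f"iou_thresh must be in (0, 1), got {iou_thresh}")
    candidates: list[tuple[float, float, int, int]] = []
    for i, p in enumerate(preds):
        for j, g in enumerate(gts):
            v = iou(p, g)
            if v >= iou_thresh:
                score = p.score if p.score is not None else 0.0
                candidates.append((v, score, i, j))
    # descending IoU, then descending score, then pred input order
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for v, _score, i, j in candidates:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        pairs.append((i, j, v))
    tp = len(pairs)
    counts = MatchCounts(tp=tp, fp=len(preds) - tp, fn=len(gts) - tp)
    return counts, pairs


def precision_recall_f1(c: MatchCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 from match counts.

    A zero denominator yields 0 by convention, so empty classes do not
    poison aggregate reports.
    """
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


def pr_curve(
    preds: Sequence[Box],
    gts: Sequence[Box],
    iou_thresh: float = 0.5,
) -> list[PRPoint]:
    """Precision-recall points at every distinct score cutoff.

    Predictions are ranked by descending confidence; each cutoff keeps
    the predictions scoring >= it and re-matches against the ground
    truth, so the curve is exactly the threshold sweep an operating
    point would see.
    """
    for p in preds:
        if p.score is None:
            raise ValueError("all predictions need a score for PR analysis")
    points: list[PRPoint] = []
    thresholds = sorted({p.score for p in preds}, reverse=True)  # type: ignore[type-var]
    for th in thresholds:
        kept = [p for p in preds if p.score >= th]  # type: ignore[operator]
        counts, _ = match_boxes(kept, gts, iou_thresh)
        prec, rec, _ = precision_recall_f1(counts)
        points.append(PRPoint(precision=prec, recall=rec, threshold=th))
    return points


def average_precision(
    preds: Sequence[Box],
    gts: Sequence[Box],
    iou_thresh: float = 0.5,
) -> float:
    """Area under the monotonized precision-recall curve for one class.

    All-point interpolation: precision at each recall level is replaced
    by the maximum precision at any recall >= it, and the area is the
    sum of precision x recall-increment over the swept cutoffs.
    Defined as 0 (with a warning) when there are no ground truths.
    """
    if not gts:
        if not preds:
            warnings.warn("AP of a class with no ground truths and no predictions is 0")
            return 0.0
        return 0.0
    if not preds:
        return 0.0
    points = pr_curve(preds, gts, iou_thresh)
    # sweep produces increasing recall as the cutoff drops
    recalls = np.array([0.0] + [pt.recall for pt in points])
    precisions = np.array([0.0] + [pt.precision for pt in points])
    # monotonize precision from the right
    precisions = np.maximum.accumulate(precisions[::-1])[::-1]
    return float(np.sum(np.diff(recalls) * precisions[1:]))


def mean_ap(per_class_ap: dict[str, float]) -> float:
    """Arithmetic mean of per-class AP values."""
    if not per_class_ap:
        raise ValueError("mean AP requires at least one class")
    return float(np.mean(list(per_class_ap.values())))


def evaluate_detections(
    preds: Sequence[Box],
    gts: Sequence[Box],
    iou_thresh: float = 0.5,
) -> DetectionReport:
    """Full per-class evaluation: AP per class, mAP, P/R/F1 and mean IoU.

    Boxes are split by class; F1 and average IoU aggregate the
    per-class matches at the given IoU threshold.
    """
    preds_by_cls = split_by_class(preds)
    gts_by_cls = split_by_class(gts)
    classes = sorted(set(preds_by_cls) | set(gts_by_cls))
    per_class_ap: dict[str, float] = {}
    tp = fp = fn = 0
    ious: list[float] = []
    for cls in classes:
        p = preds_by_cls.get(cls, [])
        g = gts_by_cls.get(cls, [])
        scored = all(b.score is not None for b in p)
        per_class_ap[cls] = average_precision(p, g, iou_thresh) if scored else float("nan")
        counts, pairs = match_boxes(p, g, iou_thresh)
        tp += counts.tp
        fp += counts.fp
        fn += counts.fn
        ious.extend(v for _, _, v in pairs)
    precision, recall, f1 = precision_recall_f1(MatchCounts(tp, fp, fn))
    finite_aps = {c: v for c, v in per_class_ap.items() if v == v}
    map_value = mean_ap(finite_aps) if finite_aps else 0.0
    return DetectionReport(
        per_class_ap=per_class_ap,
        map_value=map_value,
        precision=precision,
        recall=recall,
        f1=f1,
        avg_iou=float(np.mean(ious)) if ious else 0.0,
    )
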