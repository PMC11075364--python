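"""Detection scoring: IoU matching and macro-averaged precision/recall/F1.

Per class k, with TP/FP/FN counted over the whole test set,

    Precision = (1/K) * sum_k TP_k / (FP_k + TP_k) * 100%
    Recall    = (1/K) * sum_k TP_k / (FN_k + TP_k) * 100%
    F1        = 2 * Precision * Recall / (Precision + Recall)

Macro averaging weighs every class equally, which matters because defect
classes are rare.  Matching is class-aware and greedy by confidence: a
detection matches the unmatched same-class ground truth with the highest
IoU above the threshold; a well-localized detection with the *wrong* class
is a false positive of its predicted class (and leaves the ground truth a
false negative) — cross-class confusions are errors, not matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annot_io import Box
from .errors import ConfigurationError, ParameterError

__all__ = [
    "Detection",
    "ClassCounts",
    "MetricsReport",
    "iou",
    "match_detections",
    "macro_metrics",
    "evaluate_dataset",
    "detections_from_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Detection:
    """A scored model output: box + predicted label + confidence."""

    box: Box
    label: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ParameterError(f"score must be in [0, 1], got {self.score}")


@dataclass
class ClassCounts:
    """Per-class TP/FP/FN tallies, addable across images."""

    tp: dict[str, int] = field(default_factory=dict)
    fp: dict[str, int] = field(default_factory=dict)
    fn: dict[str, int] = field(default_factory=dict)

    def classes(self) -> set[str]:
        return set(self.tp) | set(self.fp) | set(self.fn)

    def get(self, name: str) -> tuple[int, int, int]:
        return (self.tp.get(name, 0), self.fp.get(name, 0), self.fn.get(name, 0))

    def add(self, other: "ClassCounts") -> "ClassCounts":
        out = ClassCounts(dict(self.tp), dict(self.fp), dict(self.fn))
        for name in other.classes():
            tp, fp, fn = other.get(name)
            out.tp[name] = out.tp.get(name, 0) + tp
            out.fp[name] = out.fp.get(name, 0) + fp
            out.fn[name] = out.fn.get(name, 0) + fn
        return out


@dataclass(frozen=True)
class MetricsReport:
    counts: ClassCounts
    k: int
    macro_precision: float  # percent
    macro_recall: float     # percent
    macro_f1: float         # percent
    per_class: dict[str, dict[str, float]]

    def summary(self) -> str:
        lines = [f"{'class':>10} {'TP':>6} {'FP':>6} {'FN':>6} "
                 f"{'P%':>7} {'R%':>7} {'F1%':>7}"]
        for name, row in sorted(self.per_class.items()):
            lines.append(
                f"{name:>10} {int(row['tp']):>6} {int(row['fp']):>6} "
                f"{int(row['fn']):>6} {row['precision']:>7.1f} "
                f"{row['recall']:>7.1f} {row['f1']:>7.1f}"
            )
        lines.append(
            f"{'macro':>10} {'':>6} {'':>6} {'':>6} "
            f"{self.macro_precision:>7.1f} {self.macro_recall:>7.1f} "
            f"{self.macro_f1:>7.1f}"
        )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(name=n, **r) for n, r in sorted(self.per_class.items())]
        rows.append(dict(name="macro", tp=np.nan, fp=np.nan, fn=np.nan,
                         precision=self.macro_precision,
                         recall=self.macro_recall, f1=self.macro_f1))
        return pd.DataFrame(rows)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two half-open boxes, in [0, 1]."""
    ix = max(0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def match_detections(gt_boxes: list[Box], detections: list[Detection],
                     iou_threshold: float = 0.5) -> ClassCounts:
    """Greedy class-aware matching by descending confidence.

    Each detection claims the unmatched ground truth of the *same* class
    with the highest IoU >= threshold; unmatched detections are FPs of
    their predicted class, unmatched ground truths FNs of their true class.
    Ties are broken by stable score-then-input-index order.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ParameterError(
            f"iou_threshold must be in (0, 1], got {iou_threshold}"
        )
    counts = ClassCounts()
    for b in gt_boxes:
        counts.fn[b.label] = counts.fn.get(b.label, 0)  # ensure class present
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, i))
    matched_gt: set[int] = set()
    for di in order:
        det = detections[di]
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gt_boxes):
            if j in matched_gt or gt.label != det.label:
                continue
            v = iou(gt, det.box)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched_gt.add(best_j)
            counts.tp[det.label] = counts.tp.get(det.label, 0) + 1
        else:
            counts.fp[det.label] = counts.fp.get(det.label, 0) + 1
    for j, gt in enumerate(gt_boxes):
        if j not in matched_gt:
            counts.fn[gt.label] = counts.fn.get(gt.label, 0) + 1
    return counts


def macro_metrics(counts: ClassCounts,
                  classes: list[str] | int | None = None) -> MetricsReport:
    """Macro-averaged precision/recall (percent) and their harmonic-mean F1.

    ``classes`` fixes the class universe (K); by default the classes present
    in the counts.  A per-class ratio with zero denominator contributes 0 to
    the average and logs a warning, keeping K fixed.
    """
    if classes is None:
        names = sorted(counts.classes())
    elif isinstance(classes, int):
        names = sorted(counts.classes())
        if len(names) != classes:
            raise ConfigurationError(
                f"counts cover {len(names)} classes, expected K={classes}"
            )
    else:
        names = list(classes)
        extra = counts.classes() - set(names)
        if extra:
            raise ConfigurationError(
                f"counts contain classes outside the declared set: {sorted(extra)}"
            )
    if not names:
        raise ConfigurationError("no classes to evaluate")
    k = len(names)

    per_class: dict[str, dict[str, float]] = {}
    p_sum = r_sum = 0.0
    for name in names:
        tp, fp, fn = counts.get(name)
        if tp + fp == 0:
            logger.warning("class %r has no predictions; precision counted as 0",
                           name)
            prec = 0.0
        else:
            prec = 100.0 * tp / (tp + fp)
        if tp + fn == 0:
            logger.warning("class %r has no ground truth; recall counted as 0",
                           name)
            rec = 0.0
        else:
            rec = 100.0 * tp / (tp + fn)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class[name] = dict(tp=tp, fp=fp, fn=fn, precision=prec,
                               recall=rec, f1=f1)
        p_sum += prec
        r_sum += rec

    macro_p = p_sum / k
    macro_r = r_sum / k
    macro_f1 = (2 * macro_p * macro_r / (macro_p + macro_r)
                if macro_p + macro_r > 0 else 0.0)
    return MetricsReport(counts=counts, k=k, macro_precision=macro_p,
                         macro_recall=macro_r, macro_f1=macro_f1,
                         per_class=per_class)


def detections_from_frame(frame: pd.DataFrame) -> dict[str, list[Detection]]:
    """Group a detections table (image_id, label, score, x/y min/max) by image."""
    required = {"image_id", "label", "score", "x_min", "y_min", "x_max", "y_max"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"detections table lacks columns {sorted(missing)}")
    out: dict[str, list[Detection]] = {}
    for row in frame.itertuples(index=False):
        box = Box(int(row.x_min), int(row.y_min), int(row.x_max),
                  int(row.y_max), str(row.label))
        out.setdefault(str(row.image_id), []).append(
            Detection(box=box, label=str(row.label), score=float(row.score))
        )
    return out


def evaluate_dataset(gt_by_image: dict[str, list[Box]],
                     detections: dict[str, list[Detection]] | pd.DataFrame,
                     iou_threshold: float = 0.5,
                     classes: list[str] | None = None
                     ) -> tuple[MetricsReport, pd.DataFrame]:
    """Accumulate counts over all images, then compute macro metrics once.

    Returns the report plus a per-image TP/FP/FN breakdown.  Every detection
    must reference an image present in the ground truth.
    """
    if isinstance(detections, pd.DataFrame):
        detections = detections_from_frame(detections)
    unknown = set(detections) - set(gt_by_image)
    if unknown:
        raise ConfigurationError(
            f"detections reference unknown image ids: {sorted(unknown)}"
        )
    total = ClassCounts()
    rows = []
    for image_id in sorted(gt_by_image):
        counts = match_detections(gt_by_image[image_id],
                                  detections.get(image_id, []),
                                  iou_threshold)
        total = total.add(counts)
        tp = sum(counts.tp.values())
        fp = sum(counts.fp.values())
        fn = sum(counts.fn.values())
        rows.append(dict(image_id=image_id, tp=tp, fp=fp, fn=fn))
    report = macro_metrics(total, classes=classes)
    return report, pd.DataFrame(rows, columns=["image_id", "tp", "fp", "fn"])
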