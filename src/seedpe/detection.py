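"""Detection post-processing and evaluation operators.

Implements the standard box-level machinery used to score an object
detector without needing the detector itself: IoU, confidence filtering,
greedy per-class non-maximum suppression, score-ordered prediction to
ground-truth matching with per-class mean IoU, and COCO-style average
precision (101-point interpolation, IoU thresholds 0.50:0.05:0.95, macro
averaging over classes).

Determinism: ties in score are broken by input order, ties in IoU by lowest
ground-truth index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boxes import CLASS_LABELS, BoundingBox

COCO_IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, symmetric."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def filter_and_nms(
    boxes: list[BoundingBox],
    confidence_floor: float = 0.1,
    iou_threshold: float = 0.5,
) -> list[BoundingBox]:
    """Confidence filter then greedy per-class NMS.

    Boxes scoring below ``confidence_floor`` are dropped. Remaining boxes
    are processed per class in descending score order; a box is kept iff
    its IoU with every already-kept box of the same class is strictly below
    ``iou_threshold``. Output is in descending score order (score ties keep
    input order).
    """
    scored = [(b.confidence, i, b) for i, b in enumerate(boxes)]
    if any(s is None for s, _, _ in scored):
        raise ValueError("filter_and_nms requires every box to carry a confidence")
    survivors = [(s, i, b) for s, i, b in scored if s >= confidence_floor]
    survivors.sort(key=lambda t: (-t[0], t[1]))
    kept: list[BoundingBox] = []
    for _, _, b in survivors:
        if all(
            iou(b, k) < iou_threshold
            for k in kept
            if k.class_label == b.class_label
        ):
            kept.append(b)
    return kept


@dataclass
class MatchResult:
    """Score-ordered greedy matching of predictions onto ground truth."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    unmatched_predictions: list[int] = field(default_factory=list)
    unmatched_ground_truth: list[int] = field(default_factory=list)


def match_and_miou(
    predictions: list[BoundingBox],
    ground_truth: list[BoundingBox],
    match_iou: float = 0.5,
) -> tuple[MatchResult, dict[str, float]]:
    """Match predictions to ground truth per class and report mean IoU.

    Predictions are visited in descending score order; each is matched to
    the unused same-class ground-truth box of highest IoU provided that IoU
    is at least ``match_iou``. Per-class mIoU is the mean IoU of matched
    pairs; classes with zero matches are reported as NaN and excluded from
    the macro mean (with a warning).
    """
    result = MatchResult()
    used_gt: set[int] = set()
    order = sorted(
        range(len(predictions)),
        key=lambda i: (-(predictions[i].confidence or 0.0), i),
    )
    for pi in order:
        p = predictions[pi]
        best_iou, best_gi = 0.0, None
        for gi, g in enumerate(ground_truth):
            if gi in used_gt or g.class_label != p.class_label:
                continue
            v = iou(p, g)
            if v > best_iou:  # IoU ties resolve to the lowest GT index
                best_iou, best_gi = v, gi
        if best_gi is not None and best_iou >= match_iou:
            used_gt.add(best_gi)
            result.pairs.append((pi, best_gi, best_iou))
        else:
            result.unmatched_predictions.append(pi)
    result.unmatched_ground_truth = [
        gi for gi in range(len(ground_truth)) if gi not in used_gt
    ]

    miou: dict[str, float] = {}
    for cls in CLASS_LABELS:
        ious = [v for pi, gi, v in result.pairs if predictions[pi].class_label == cls]
        present = any(g.class_label == cls for g in ground_truth) or any(
            p.class_label == cls for p in predictions
        )
        if ious:
            miou[cls] = float(np.mean(ious))
        elif present:
            warnings.warn(f"class {cls}: no matched pairs, mIoU undefined", stacklevel=2)
            miou[cls] = float("nan")
    return result, miou


@dataclass
class DetectionMetrics:
    miou_per_class: dict[str, float]
    miou_macro: float
    ap_per_class: dict[str, float]
    map_macro: float
    ap50: float
    ap75: float


def _ap_one_class(
    predictions: list[tuple[int, BoundingBox]],
    ground_truth: list[tuple[int, BoundingBox]],
    iou_threshold: float,
) -> float:
    """COCO 101-point interpolated AP for one class at one IoU threshold.

    ``predictions``/``ground_truth`` carry (image index, box); ranking is
    global by score but matches are confined within an image.
    """
    n_gt = len(ground_truth)
    if n_gt == 0:
        return float("nan")
    order = sorted(
        range(len(predictions)),
        key=lambda i: (-(predictions[i][1].confidence or 0.0), i),
    )
    used: set[int] = set()
    tp = np.zeros(len(order))
    for rank, pi in enumerate(order):
        img, p = predictions[pi]
        best_iou, best_gi = 0.0, None
        for gi, (gimg, g) in enumerate(ground_truth):
            if gimg != img or gi in used:
                continue
            v = iou(p, g)
            if v > best_iou:
                best_iou, best_gi = v, gi
        if best_gi is not None and best_iou >= iou_threshold:
            used.add(best_gi)
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(order) + 1)
    recall = cum_tp / n_gt
    # interpolated precision: max precision at recall >= r
    recall_grid = np.linspace(0.0, 1.0, 101)
    precision_envelope = np.maximum.accumulate(precision[::-1])[::-1]
    interp = np.zeros_like(recall_grid)
    for k, r in enumerate(recall_grid):
        idx = np.searchsorted(recall, r, side="left")
        if idx < len(precision_envelope):
            interp[k] = precision_envelope[idx]
    return float(interp.mean())


def average_precision(
    predictions: list[list[BoundingBox]],
    ground_truth: list[list[BoundingBox]],
    iou_thresholds: tuple[float, ...] = COCO_IOU_THRESHOLDS,
    match_iou: float = 0.5,
) -> DetectionMetrics:
    """COCO-style evaluation over a list of images.

    ``predictions[i]`` and ``ground_truth[i]`` are the scored detections
    and annotations of image ``i``. Reports per-class AP averaged over
    ``iou_thresholds``, the macro mAP, AP50/AP75 macro values, and the
    matched-pair mIoU at ``match_iou``. Classes absent from the ground
    truth are excluded from macro averages with a warning.
    """
    if len(predictions) != len(ground_truth):
        raise ValueError("predictions and ground_truth must cover the same images")

    by_class_pred: dict[str, list] = {c: [] for c in CLASS_LABELS}
    by_class_gt: dict[str, list] = {c: [] for c in CLASS_LABELS}
    for img, (preds, gts) in enumerate(zip(predictions, ground_truth)):
        for b in preds:
            by_class_pred[b.class_label].append((img, b))
        for b in gts:
            by_class_gt[b.class_label].append((img, b))

    ap_per_class: dict[str, float] = {}
    ap50_c: dict[str, float] = {}
    ap75_c: dict[str, float] = {}
    for cls in CLASS_LABELS:
        if not by_class_gt[cls]:
            if by_class_pred[cls]:
                warnings.warn(
                    f"class {cls}: no ground truth, AP undefined", stacklevel=2
                )
            continue
        aps = [
            _ap_one_class(by_class_pred[cls], by_class_gt[cls], t)
            for t in iou_thresholds
        ]
        ap_per_class[cls] = float(np.mean(aps))
        ap50_c[cls] = _ap_one_class(by_class_pred[cls], by_class_gt[cls], 0.50)
        ap75_c[cls] = _ap_one_class(by_class_pred[cls], by_class_gt[cls], 0.75)

    # matched-pair mIoU, pooled across images at the matching threshold
    miou_acc: dict[str, list[float]] = {c: [] for c in CLASS_LABELS}
    for preds, gts in zip(predictions, ground_truth):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, miou = match_and_miou(preds, gts, match_iou)
        for cls, v in miou.items():
            if not np.isnan(v):
                miou_acc[cls].append(v)
    miou_per_class = {
        c: float(np.mean(vs)) for c, vs in miou_acc.items() if vs
    }

    def _macro(d: dict[str, float]) -> float:
        vals = [v for v in d.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return DetectionMetrics(
        miou_per_class=miou_per_class,
        miou_macro=_macro(miou_per_class),
        ap_per_class=ap_per_class,
        map_macro=_macro(ap_per_class),
        ap50=_macro(ap50_c),
        ap75=_macro(ap75_c),
    )
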