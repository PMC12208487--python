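"""Annotation-quality evaluation against a gold standard.

Pipeline for auditing a candidate annotation set (junior physicians or model
pre-annotations) against reviewed gold labels: confidence filtering and
class-agnostic NMS of detections, greedy IoU matching, confusion matrices
with an explicit background row/column (so false detections and misses are
visible), per-class/overall accuracy, and mAP50 / mAP50-95.

Matching is class-blind — class disagreements are exactly what the confusion
matrix measures — while average precision is computed per class, as is
standard for detection metrics.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .yolo_dataset import LabeledBox

__all__ = [
    "MatchResult",
    "ConfusionMatrix",
    "iou",
    "class_agnostic_nms",
    "filter_confidence",
    "match_to_gold",
    "confusion",
    "accuracy",
    "mean_average_precision",
]

MAP_COCO_THRESHOLDS = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))


@dataclasses.dataclass
class MatchResult:
    pairs: list[tuple[LabeledBox, LabeledBox, float]]  # (candidate, gold, IoU)
    unmatched_candidates: list[LabeledBox]  # false detections
    unmatched_gold: list[LabeledBox]  # missed nodules


@dataclasses.dataclass
class ConfusionMatrix:
    """(C+1)×(C+1) table; rows = candidate class, columns = gold class.

    The last row/column is background: row counts missed gold boxes, column
    counts false detections.  ``proportions`` is column-normalized.
    """

    counts: np.ndarray
    class_names: list[str]

    @property
    def background_index(self) -> int:
        return len(self.class_names)

    @property
    def proportions(self) -> np.ndarray:
        totals = self.counts.sum(axis=0, keepdims=True).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = self.counts / totals
        return np.where(totals > 0, prop, 0.0)


def iou(a: LabeledBox, b: LabeledBox) -> float:
    """Intersection-over-union in normalized coordinates; 0 when disjoint."""
    a, b = a.clipped(), b.clipped()
    ax0, ay0, ax1, ay1 = a.x0, a.y0, a.x1, a.y1
    bx0, by0, bx1, by1 = b.x0, b.y0, b.x1, b.y1
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def filter_confidence(
    boxes: list[LabeledBox], conf_threshold: float = 0.1
) -> list[LabeledBox]:
    """Keep boxes with confidence >= threshold, order preserved."""
    for b in boxes:
        if b.confidence is None:
            raise ValueError("all boxes must carry a confidence score")
    return [b for b in boxes if b.confidence >= conf_threshold]


def class_agnostic_nms(
    boxes: list[LabeledBox], iou_threshold: float = 0.7
) -> list[LabeledBox]:
    """Greedy NMS across all classes.

    Repeatedly keep the highest-confidence remaining box and discard every
    remaining box (any class) with IoU strictly above the threshold against
    it.  Output is sorted by confidence descending; ties broken by input
    order for determinism.
    """
    for b in boxes:
        if b.confidence is None:
            raise ValueError("all boxes must carry a confidence score")
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].confidence, i))
    kept: list[LabeledBox] = []
    suppressed = [False] * len(boxes)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(boxes[i])
        for j in order:
            if j != i and not suppressed[j] and iou(boxes[i], boxes[j]) > iou_threshold:
                suppressed[j] = True
    return kept


def match_to_gold(
    candidates: list[LabeledBox],
    gold: list[LabeledBox],
    match_iou: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching by descending IoU, class-blind.

    Ties are broken by candidate list order, then gold list order, so the
    result is deterministic.
    """
    scored = []
    for ci, c in enumerate(candidates):
        for gi, g in enumerate(gold):
            v = iou(c, g)
            if v >= match_iou:
                scored.append((v, ci, gi))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_c: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for v, ci, gi in scored:
        if ci in used_c or gi in used_g:
            continue
        used_c.add(ci)
        used_g.add(gi)
        pairs.append((candidates[ci], gold[gi], v))
    return MatchResult(
        pairs=pairs,
        unmatched_candidates=[c for i, c in enumerate(candidates) if i not in used_c],
        unmatched_gold=[g for i, g in enumerate(gold) if i not in used_g],
    )


def confusion(matches: list[MatchResult], class_names: list[str]) -> ConfusionMatrix:
    """Aggregate match results into a confusion matrix with background."""
    C = len(class_names)
    counts = np.zeros((C + 1, C + 1), dtype=np.int64)

    def _check(cid: int) -> int:
        if not 0 <= cid < C:
            raise ValueError(f"class id {cid} out of range [0, {C})")
        return cid

    for m in matches:
        for cand, gold, _ in m.pairs:
            counts[_check(cand.class_id), _check(gold.class_id)] += 1
        for gold in m.unmatched_gold:
            counts[C, _check(gold.class_id)] += 1  # missed -> background row
        for cand in m.unmatched_candidates:
            counts[_check(cand.class_id), C] += 1  # false detection
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def accuracy(matrix: ConfusionMatrix) -> tuple[dict[str, float], float]:
    """Per-class and overall accuracy over gold columns.

    Per-class accuracy is diagonal / gold-column total, so a missed gold
    nodule counts as an error; overall accuracy is total diagonal / total
    gold nodules, which equals the count-weighted mean of per-class values.
    """
    C = len(matrix.class_names)
    gold_totals = matrix.counts[:, :C].sum(axis=0)
    if gold_totals.sum() == 0:
        raise ValueError("no gold boxes: accuracy undefined")
    diag = np.diag(matrix.counts)[:C]
    per_class = {
        name: (diag[i] / gold_totals[i] if gold_totals[i] > 0 else float("nan"))
        for i, name in enumerate(matrix.class_names)
    }
    overall = float(diag.sum() / gold_totals.sum())
    return per_class, overall


def _average_precision(
    detections: list[tuple[int, float, LabeledBox]],
    gold_by_image: dict[int, list[LabeledBox]],
    iou_threshold: float,
) -> float:
    """All-points-interpolated AP for one class at one IoU threshold.

    ``detections`` holds (image index, confidence, box) for one class;
    ``gold_by_image`` holds that class's gold boxes per image.
    """
    n_gold = sum(len(v) for v in gold_by_image.values())
    if n_gold == 0:
        return float("nan")
    dets = sorted(detections, key=lambda t: (-t[1], t[0]))
    matched: dict[int, list[bool]] = {
        img: [False] * len(v) for img, v in gold_by_image.items()
    }
    tp = np.zeros(len(dets))
    fp = np.zeros(len(dets))
    for k, (img, _conf, box) in enumerate(dets):
        golds = gold_by_image.get(img, [])
        best_iou, best_gi = 0.0, -1
        for gi, g in enumerate(golds):
            v = iou(box, g)
            if v > best_iou:
                best_iou, best_gi = v, gi
        if best_gi >= 0 and best_iou >= iou_threshold and not matched[img][best_gi]:
            matched[img][best_gi] = True
            tp[k] = 1
        else:
            fp[k] = 1
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(fp)
    recall = tp_cum / n_gold
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    # all-points interpolation: precision envelope integrated over recall
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def mean_average_precision(
    candidates_per_image: list[list[LabeledBox]],
    gold_per_image: list[list[LabeledBox]],
    iou_thresholds: tuple[float, ...] = MAP_COCO_THRESHOLDS,
) -> tuple[dict[float, float], float, float]:
    """Per-class AP averaged over classes with >= 1 gold instance.

    Returns ``(mAP per threshold, mAP50, mAP50-95)``; mAP50-95 is the mean
    over the 0.5:0.05:0.95 thresholds present in ``iou_thresholds``.
    """
    if len(candidates_per_image) != len(gold_per_image):
        raise ValueError("candidate and gold lists must be parallel per image")
    classes = sorted(
        {b.class_id for boxes in gold_per_image for b in boxes}
    )
    per_threshold: dict[float, float] = {}
    for thr in iou_thresholds:
        aps = []
        for c in classes:
            dets = [
                (img, b.confidence if b.confidence is not None else 1.0, b)
                for img, boxes in enumerate(candidates_per_image)
                for b in boxes
                if b.class_id == c
            ]
            gold_c = {
                img: [b for b in boxes if b.class_id == c]
                for img, boxes in enumerate(gold_per_image)
            }
            aps.append(_average_precision(dets, gold_c, thr))
        per_threshold[float(thr)] = float(np.nanmean(aps)) if aps else 0.0
    map50 = per_threshold.get(0.5, float("nan"))
    coco = [per_threshold[t] for t in MAP_COCO_THRESHOLDS if t in per_threshold]
    map50_95 = float(np.mean(coco)) if coco else float("nan")
    return per_threshold, map50, map50_95
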