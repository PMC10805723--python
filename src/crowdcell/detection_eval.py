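"""Detection scoring: IoU matching, pooled TPR/PPV/F1, AP50 and AP@[.5:.95].

The protocol mirrors how cell detectors are tested on sparse classes:
predictions below a confidence threshold (default 0.25) are discarded,
remaining boxes are matched greedily in confidence order to unmatched
ground-truth boxes of the same class at IoU >= 0.35, and counts are pooled
over the whole test set before computing TPR/PPV/F1 (per-image averaging is
meaningless when single images hold very few astrocytes).  Average precision
uses all-points interpolation of the precision envelope and, by convention,
no confidence floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .boxes import BBox, LabelSet
from .quality import MatchResult, PRFReport, prf

logger = logging.getLogger(__name__)

DEFAULT_AP_THRESHOLDS = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class EvalConfig:
    confidence_min: float = 0.25
    iou_min: float = 0.35
    ap_thresholds: tuple[float, ...] = DEFAULT_AP_THRESHOLDS

    def __post_init__(self) -> None:
        for t in (self.iou_min, *self.ap_thresholds):
            if not 0 < t <= 1:
                raise ValueError("IoU thresholds must lie in (0, 1]")
        if list(self.ap_thresholds) != sorted(self.ap_thresholds):
            raise ValueError("ap_thresholds must be sorted ascending")


@dataclass
class DetectionReport:
    per_class: dict[str, dict[str, float | int | None]]
    mean: dict[str, float | None]


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two half-open boxes."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _conf(b: BBox) -> float:
    return b.confidence if b.confidence is not None else 1.0


def _greedy_match(preds: Sequence[BBox], gts: Sequence[BBox],
                  iou_min: float) -> list[int | None]:
    """For confidence-desc-sorted ``preds``, the matched gt index (or None):
    each prediction takes the unmatched gt with the highest IoU >= iou_min."""
    taken = [False] * len(gts)
    out: list[int | None] = []
    for p in preds:
        best_j, best_iou = None, iou_min
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            v = iou(p, g)
            if v > best_iou or (v == best_iou and best_j is None and v >= iou_min):
                best_j, best_iou = j, v
        if best_j is not None and best_iou >= iou_min:
            taken[best_j] = True
        out.append(best_j)
    return out


def match_detections(preds: Sequence[BBox], gts: Sequence[BBox],
                     config: EvalConfig = EvalConfig()
                     ) -> dict[str, MatchResult]:
    """Per-class one-to-one matching after the confidence filter."""
    classes = sorted({b.cell_class for b in preds}
                     | {b.cell_class for b in gts})
    results = {}
    for cls in classes:
        p = [b for b in preds if b.cell_class == cls
             and _conf(b) >= config.confidence_min]
        p.sort(key=lambda b: (-_conf(b), b.x_min, b.y_min))
        g = [b for b in gts if b.cell_class == cls]
        assigned = _greedy_match(p, g, config.iou_min)
        pairs = [(i, j) for i, j in enumerate(assigned) if j is not None]
        tp = len(pairs)
        results[cls] = MatchResult(pairs=pairs, tp=tp, fp=len(p) - tp,
                                   fn=len(g) - tp)
    return results


def _ranked(preds: Sequence[tuple[object, BBox]]):
    return sorted(preds, key=lambda ib: (-_conf(ib[1]), str(ib[0]),
                                         ib[1].x_min, ib[1].y_min))


def _ap_from_flags(flags: Sequence[bool], n_gt: int) -> float:
    """All-points-interpolated AP from ranked hit/miss flags."""
    if n_gt == 0:
        raise ValueError("AP undefined without ground-truth boxes")
    if not flags:
        return 0.0
    tp = np.cumsum(np.asarray(flags, dtype=float))
    fp = np.cumsum(~np.asarray(flags, dtype=bool))
    recall = tp / n_gt
    precision = tp / (tp + fp)
    mrec = np.concatenate(([0.0], recall))
    mpre = np.concatenate(([1.0], precision))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    return float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))


def average_precision(preds: Sequence[BBox], gts: Sequence[BBox],
                      iou_threshold: float) -> float:
    """AP of a single class at one IoU threshold (no confidence floor).

    Predictions are ranked by confidence (ties by position), greedily
    matched, and the precision envelope is integrated over recall.
    """
    ranked = _ranked(list(enumerate(preds)))
    assigned = _greedy_match([b for _, b in ranked], gts, iou_threshold)
    flags = [j is not None for j in assigned]
    return _ap_from_flags(flags, len(gts))


def ap_range(preds: Sequence[BBox], gts: Sequence[BBox],
             thresholds: Sequence[float] = DEFAULT_AP_THRESHOLDS) -> float:
    """Unweighted mean AP over a ladder of IoU thresholds."""
    return float(np.mean([average_precision(preds, gts, t)
                          for t in thresholds]))


def _pooled_ap(preds_by_image: Mapping[str, Sequence[BBox]],
               gts_by_image: Mapping[str, Sequence[BBox]],
               threshold: float) -> float | None:
    """AP over a pooled multi-image test set (matching stays per image)."""
    n_gt = sum(len(g) for g in gts_by_image.values())
    if n_gt == 0:
        return None
    ranked = _ranked([(img, b) for img, boxes in sorted(preds_by_image.items())
                      for b in boxes])
    taken: dict[str, list[bool]] = {img: [False] * len(g)
                                    for img, g in gts_by_image.items()}
    flags = []
    for img, p in ranked:
        gts = gts_by_image.get(img, [])
        best_j, best_iou = None, threshold
        for j, g in enumerate(gts):
            if taken[img][j]:
                continue
            v = iou(p, g)
            if v >= threshold and (best_j is None or v > best_iou):
                best_j, best_iou = j, v
        if best_j is not None:
            taken[img][best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return _ap_from_flags(flags, n_gt)


def evaluate_suite(pred_sets: Mapping[str, Sequence[BBox]] | Sequence[LabelSet],
                   gt_sets: Mapping[str, Sequence[BBox]] | Sequence[LabelSet],
                   config: EvalConfig = EvalConfig()) -> DetectionReport:
    """Score a prediction pool against a ground-truth pool.

    TP/FP/FN are pooled over all images per class before TPR/PPV/F1; AP50
    and the AP ladder are computed on the pooled ranking.  Classes without
    any ground-truth box get no AP and are excluded from the AP means with
    a warning.
    """
    def _as_map(sets):
        if isinstance(sets, Mapping):
            return {k: list(v) for k, v in sets.items()}
        return {ls.image_id: list(ls.boxes) for ls in sets}

    preds = _as_map(pred_sets)
    gts = _as_map(gt_sets)
    if set(preds) != set(gts):
        raise ValueError("prediction and ground-truth image ids differ: "
                         f"{sorted(set(preds) ^ set(gts))}")

    classes = sorted({b.cell_class for boxes in list(preds.values())
                      + list(gts.values()) for b in boxes})
    per_class: dict[str, dict] = {}
    for cls in classes:
        tp = fp = fn = 0
        for img in sorted(gts):
            m = match_detections(
                [b for b in preds[img] if b.cell_class == cls],
                [b for b in gts[img] if b.cell_class == cls], config)
            for r in m.values():
                tp += r.tp
                fp += r.fp
                fn += r.fn
        report = prf(MatchResult.from_counts(tp, fp, fn))
        p_cls = {img: [b for b in boxes if b.cell_class == cls]
                 for img, boxes in preds.items()}
        g_cls = {img: [b for b in boxes if b.cell_class == cls]
                 for img, boxes in gts.items()}
        ap50 = _pooled_ap(p_cls, g_cls, 0.50)
        if ap50 is None:
            logger.warning("class %r has no ground-truth boxes; AP excluded",
                           cls)
            apr = None
        else:
            aps = [_pooled_ap(p_cls, g_cls, t) for t in config.ap_thresholds]
            apr = float(np.mean([a for a in aps if a is not None]))
        per_class[cls] = {"tp": tp, "fp": fp, "fn": fn,
                          "tpr": report.tpr, "ppv": report.ppv,
                          "f1": report.f1, "ap50": ap50, "ap_range": apr}

    def _mean(key):
        vals = [v[key] for v in per_class.values() if v[key] is not None]
        return float(np.mean(vals)) if vals else None

    mean = {k: _mean(k) for k in ("tpr", "ppv", "f1", "ap50", "ap_range")}
    return DetectionReport(per_class=per_class, mean=mean)
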