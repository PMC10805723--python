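"""Quality control of point annotations against expert ground truth.

Point predictions are matched one-to-one to ground-truth cells within a
radius (greedy, closest pair first); true/false positives and false
negatives feed recall (TPR), precision (PPV) and the F1 score.  Inter-rater
reliability is summarized by Fleiss' kappa over marked/not-marked ratings of
candidate cells, and the qualification gate re-implements the annotation
platform's entry test: pooled precision of at least ``min_ppv`` on the
qualification tiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MATCH_RADIUS = 20.0  # px; ~5 um at 0.25 um/px, about a nucleus radius


def _as_xy(points) -> np.ndarray:
    if points is None:
        return np.empty((0, 2), dtype=float)
    if isinstance(points, pd.DataFrame):
        if len(points) == 0:
            return np.empty((0, 2), dtype=float)
        return points[["x", "y"]].to_numpy(dtype=float)
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        return np.empty((0, 2), dtype=float)
    return arr.reshape(-1, 2)


@dataclass
class MatchResult:
    """One-to-one point matching outcome: matched pairs and TP/FP/FN."""

    pairs: list[tuple[int, int]]
    tp: int
    fp: int
    fn: int

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "MatchResult":
        if min(tp, fp, fn) < 0:
            raise ValueError("counts must be non-negative")
        return cls(pairs=[], tp=tp, fp=fp, fn=fn)

    @property
    def wrong(self) -> int:
        """FP + FN: both inventing a cell and missing one count as wrong."""
        return self.fp + self.fn


@dataclass
class PRFReport:
    tpr: float
    ppv: float
    f1: float


def match_to_truth(pred_points, gt_points,
                   radius: float = DEFAULT_MATCH_RADIUS) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground-truth points.

    Candidate (pred, gt) pairs within ``radius`` are sorted by distance
    ascending (ties broken by pred index then gt index) and accepted when
    both sides are still unmatched.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    pred = _as_xy(pred_points)
    gt = _as_xy(gt_points)
    if len(pred) == 0 or len(gt) == 0:
        return MatchResult(pairs=[], tp=0, fp=len(pred), fn=len(gt))
    d = np.hypot(pred[:, None, 0] - gt[None, :, 0],
                 pred[:, None, 1] - gt[None, :, 1])
    pi, gi = np.nonzero(d <= radius)
    order = np.lexsort((gi, pi, d[pi, gi]))
    pred_used = np.zeros(len(pred), dtype=bool)
    gt_used = np.zeros(len(gt), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for k in order:
        i, j = int(pi[k]), int(gi[k])
        if not pred_used[i] and not gt_used[j]:
            pred_used[i] = gt_used[j] = True
            pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(pairs=pairs, tp=tp, fp=len(pred) - tp, fn=len(gt) - tp)


def prf(match: MatchResult) -> PRFReport:
    """TPR, PPV and F1 from matched counts.

    ``f1 = 2 tp / (2 tp + fp + fn)`` (Dice); with all counts zero every
    metric is defined as 0, and any single zero denominator yields 0 for
    that metric.
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    tpr = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return PRFReport(tpr=tpr, ppv=ppv, f1=f1)


def build_rating_items(annotations, gt_points,
                       radius: float = DEFAULT_MATCH_RADIUS,
                       roster: Sequence[str] | None = None) -> np.ndarray:
    """Build an items x {marked, not-marked} count table for Fleiss' kappa.

    Items are the ground-truth cells plus clusters of purely false-positive
    points (clicks no worker could have aimed at a real cell).  Each roster
    worker rates every item "marked" (one of their points matches it within
    ``radius``) or "not marked".  Every row sums to the roster size.
    """
    from .aggregation import cluster_points  # local import: avoid a cycle

    from .crowd_sim import AnnotationSet

    if isinstance(annotations, AnnotationSet):
        points = annotations.points
        roster = list(annotations.roster) if roster is None else list(roster)
    else:
        points = annotations
        if roster is None:
            roster = sorted(points["worker_id"].unique())
    gt = _as_xy(gt_points)

    # Pool each worker's unmatched points, then cluster them across workers
    # to form the false-positive items.
    fp_rows = []
    for worker in roster:
        wp = points[points["worker_id"] == worker]
        m = match_to_truth(wp, gt, radius)
        matched = {i for i, _ in m.pairs}
        for pos, (_, row) in enumerate(wp.iterrows()):
            if pos not in matched:
                fp_rows.append({"image_id": row.get("image_id", "img"),
                                "tile_id": "", "worker_id": worker,
                                "class": "fp", "x": row["x"], "y": row["y"]})
    fp_items = np.empty((0, 2))
    if fp_rows:
        fp_df = pd.DataFrame(fp_rows)
        fp_df["image_id"] = fp_df["image_id"].iloc[0]
        clusters = cluster_points(fp_df, radius=radius)
        fp_items = np.array([c.centroid for c in clusters], dtype=float)

    items = np.vstack([gt, fp_items]) if len(fp_items) else gt
    n_items = len(items)
    table = np.zeros((n_items, 2), dtype=int)
    for worker in roster:
        wp = points[points["worker_id"] == worker]
        m = match_to_truth(wp, items, radius)
        marked = {j for _, j in m.pairs}
        for j in range(n_items):
            table[j, 0 if j in marked else 1] += 1
    return table


def fleiss_kappa(table) -> float:
    """Fleiss' kappa for an items x categories count table.

    ``kappa = (P_bar - P_bar_e) / (1 - P_bar_e)``.  When expected agreement
    is 1 (a single category used throughout, which forces perfect observed
    agreement) the statistic is defined as 1.
    """
    from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1:
        raise ValueError("table must be 2-D with at least one item")
    row_sums = table.sum(axis=1)
    n = row_sums[0]
    if n < 2:
        raise ValueError("need at least 2 raters")
    if not np.allclose(row_sums, n):
        raise ValueError("all rows must sum to the same rater count")
    p_cat = table.sum(axis=0) / table.sum()
    pe = float(np.sum(p_cat ** 2))
    if 1 - pe < 1e-12:
        return 1.0
    return float(_sm_fleiss(table, method="fleiss"))


@dataclass
class GateResult:
    passed: bool
    report: PRFReport
    match: MatchResult
    no_predictions: bool = False


def qualification_gate(worker_points, gt_points,
                       radius: float = DEFAULT_MATCH_RADIUS,
                       min_ppv: float = 0.8) -> GateResult:
    """Entry test: pass iff pooled PPV on the qualification tiles is at
    least ``min_ppv`` (inclusive).  With zero predictions the PPV is
    undefined and conservatively treated as 0 (fail, flagged)."""
    match = match_to_truth(worker_points, gt_points, radius)
    report = prf(match)
    no_pred = (match.tp + match.fp) == 0
    passed = (not no_pred) and report.ppv >= min_ppv
    logger.info("qualification gate: ppv=%.3f (min %.2f) -> %s",
                report.ppv, min_ppv, "pass" if passed else "fail")
    return GateResult(passed=passed, report=report, match=match,
                      no_predictions=no_pred)
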