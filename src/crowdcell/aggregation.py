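"""Consensus over crowd point annotations: majority and weighted vote.

Same-class clicks from different workers are grouped into clusters (greedy
nearest-pair agglomeration with at most one point per worker per cluster);
a cluster becomes an accepted consensus cell when a strict majority of the
task roster clicked it, or — for the weighted vote — when the weight mass of
its members exceeds half the roster's total weight.  Worker weights come
from a hidden ground-truth image: starting from 1.00, each wrong cell
(false positive or missed cell) costs 0.20, floored at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quality import DEFAULT_MATCH_RADIUS, MatchResult, match_to_truth

DEFAULT_CLUSTER_RADIUS = 20.0  # px; ~5 um, about a nucleus radius

WEIGHT_START = 1.00
WEIGHT_PENALTY = 0.20
WEIGHT_FLOOR = 0.05

CONSENSUS_COLUMNS = ["image_id", "class", "x", "y", "support", "weight_sum",
                     "accepted", "rule"]


@dataclass
class Cluster:
    """Same-class clicks from distinct workers grouped as one candidate cell."""

    cluster_id: int
    image_id: str
    cell_class: str
    members: pd.DataFrame  # columns include worker_id, x, y
    centroid: tuple[float, float]

    @property
    def support(self) -> int:
        return len(self.members)

    @property
    def workers(self) -> set[str]:
        return set(self.members["worker_id"])


@dataclass
class WorkerWeight:
    worker_id: str
    wrong_count: int
    weight: float


def cluster_points(points: pd.DataFrame,
                   radius: float = DEFAULT_CLUSTER_RADIUS) -> list[Cluster]:
    """Greedy nearest-pair agglomeration of one image's same-class points.

    Candidate inter-worker pairs are sorted by distance ascending (ties by
    worker ids, then coordinates) and merged iff the merged cluster keeps at
    most one point per worker and every member lies strictly within
    ``radius`` of the merged centroid (so two clicks exactly ``2 * radius``
    apart stay separate).  Every point ends up in exactly one cluster.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if len(points) == 0:
        return []
    if points["class"].nunique() > 1:
        raise ValueError("cluster_points expects a single class")
    if "image_id" in points.columns and points["image_id"].nunique() > 1:
        raise ValueError("cluster_points expects a single image")

    pts = points.reset_index(drop=True)
    xy = pts[["x", "y"]].to_numpy(float)
    workers = pts["worker_id"].astype(str).to_list()
    n = len(pts)

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    members: dict[int, list[int]] = {i: [i] for i in range(n)}

    from scipy.spatial import cKDTree

    tree = cKDTree(xy)
    cand = []
    for a, b in tree.query_pairs(2 * radius):
        if workers[a] == workers[b]:
            continue
        d = float(np.hypot(*(xy[a] - xy[b])))
        key = (d, min(workers[a], workers[b]), max(workers[a], workers[b]),
               *np.minimum(xy[a], xy[b]), *np.maximum(xy[a], xy[b]))
        cand.append((key, a, b))
    cand.sort(key=lambda t: t[0])

    for _, a, b in cand:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        merged = members[ra] + members[rb]
        ws = [workers[i] for i in merged]
        if len(set(ws)) != len(ws):
            continue
        centroid = xy[merged].mean(axis=0)
        if np.all(np.hypot(*(xy[merged] - centroid).T) < radius):
            parent[rb] = ra
            members[ra] = merged
            del members[rb]

    image_id = str(pts["image_id"].iloc[0]) if "image_id" in pts.columns else ""
    cell_class = str(pts["class"].iloc[0])
    clusters = []
    roots = sorted(members, key=lambda r: (xy[members[r]].mean(axis=0)[0],
                                           xy[members[r]].mean(axis=0)[1]))
    for cid, root in enumerate(roots):
        sub = pts.loc[members[root]].copy()
        centroid = xy[members[root]].mean(axis=0)
        clusters.append(Cluster(cluster_id=cid, image_id=image_id,
                                cell_class=cell_class, members=sub,
                                centroid=(float(centroid[0]),
                                          float(centroid[1]))))
    return clusters


def majority_vote(clusters: Sequence[Cluster], roster_size: int,
                  threshold: float = 0.5) -> pd.DataFrame:
    """Strict-majority consensus: accepted iff support > threshold * roster.

    Consensus coordinates are the unweighted member centroid.  Returns the
    full consensus table (accepted and rejected clusters).
    """
    if roster_size < 1:
        raise ValueError("roster_size must be >= 1")
    rows = []
    for c in clusters:
        if c.support > roster_size:
            raise ValueError(
                f"cluster support {c.support} exceeds roster {roster_size}")
        rows.append({"image_id": c.image_id, "class": c.cell_class,
                     "x": c.centroid[0], "y": c.centroid[1],
                     "support": c.support, "weight_sum": np.nan,
                     "accepted": c.support > threshold * roster_size,
                     "rule": "MV"})
    return pd.DataFrame(rows, columns=CONSENSUS_COLUMNS)


def worker_weight(worker_points, gt_points,
                  match_radius: float = DEFAULT_MATCH_RADIUS,
                  worker_id: str = "") -> WorkerWeight:
    """Voting weight of one worker from the hidden ground-truth image.

    ``weight = max(0.05, 1.00 - 0.20 * wrong)`` where ``wrong`` counts both
    false positives and missed cells of the one-to-one point matching.
    """
    match = match_to_truth(worker_points, gt_points, match_radius)
    wrong = match.wrong
    weight = max(WEIGHT_FLOOR, WEIGHT_START - WEIGHT_PENALTY * wrong)
    return WorkerWeight(worker_id=worker_id, wrong_count=wrong,
                        weight=float(weight))


def compute_weights(annotations, gt_points,
                    match_radius: float = DEFAULT_MATCH_RADIUS
                    ) -> dict[str, WorkerWeight]:
    """Weights for every roster worker of a ground-truth-image annotation
    set.  A worker absent from the set still gets a weight (every missed
    cell counts as wrong)."""
    from .crowd_sim import AnnotationSet

    if isinstance(annotations, AnnotationSet):
        points, roster = annotations.points, annotations.roster
    else:
        points = annotations
        roster = sorted(points["worker_id"].unique())
    return {w: worker_weight(points[points["worker_id"] == w], gt_points,
                             match_radius, worker_id=w)
            for w in roster}


def weighted_vote(clusters: Sequence[Cluster],
                  weights: Mapping[str, float | WorkerWeight],
                  roster: Sequence[str],
                  threshold: float = 0.5) -> pd.DataFrame:
    """Weighted-vote consensus: accepted iff the member weight sum exceeds
    ``threshold`` times the total roster weight; coordinates are the
    weight-weighted member centroid."""
    w = {k: (v.weight if isinstance(v, WorkerWeight) else float(v))
         for k, v in weights.items()}
    missing = [r for r in roster if r not in w]
    if missing:
        raise KeyError(f"no weight for roster workers {missing}")
    total = sum(w[r] for r in roster)
    rows = []
    for c in clusters:
        try:
            mw = np.array([w[wid] for wid in c.members["worker_id"]])
        except KeyError as exc:
            raise KeyError(f"no weight for worker {exc.args[0]!r}") from exc
        xy = c.members[["x", "y"]].to_numpy(float)
        centroid = (xy * mw[:, None]).sum(axis=0) / mw.sum()
        rows.append({"image_id": c.image_id, "class": c.cell_class,
                     "x": float(centroid[0]), "y": float(centroid[1]),
                     "support": c.support, "weight_sum": float(mw.sum()),
                     "accepted": mw.sum() > threshold * total,
                     "rule": "WV"})
    return pd.DataFrame(rows, columns=CONSENSUS_COLUMNS)


def weights_frame(weights: Mapping[str, WorkerWeight]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"worker_id": k, "wrong_count": v.wrong_count, "weight": v.weight}
         for k, v in sorted(weights.items())],
        columns=["worker_id", "wrong_count", "weight"])
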