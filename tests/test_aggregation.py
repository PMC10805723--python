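"""Clustering and vote aggregation: rules, weight scheme, oracle checks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crowdcell import (cluster_points, compute_weights, majority_vote,
                       weighted_vote, worker_weight)

from conftest import gt_points


def points_df(rows):
    return pd.DataFrame(rows, columns=["image_id", "tile_id", "worker_id",
                                       "class", "x", "y"])


class TestClusterPoints:
    def test_coincident_clicks_form_one_cluster(self):
        pts = points_df([("i", "", "w0", "tumor", 10.0, 10.0),
                         ("i", "", "w1", "tumor", 10.0, 10.0)])
        clusters = cluster_points(pts, radius=20)
        assert len(clusters) == 1
        assert clusters[0].support == 2
        assert clusters[0].centroid == (10.0, 10.0)

    def test_points_two_radii_apart_stay_separate(self):
        pts = points_df([("i", "", "w0", "tumor", 0.0, 0.0),
                         ("i", "", "w1", "tumor", 40.0, 0.0)])
        assert len(cluster_points(pts, radius=20)) == 2

    def test_same_worker_points_never_share_a_cluster(self):
        pts = points_df([("i", "", "w0", "tumor", 0.0, 0.0),
                         ("i", "", "w0", "tumor", 1.0, 0.0),
                         ("i", "", "w1", "tumor", 0.5, 0.0)])
        clusters = cluster_points(pts, radius=20)
        assert sorted(c.support for c in clusters) == [1, 2]

    def test_mixed_classes_rejected(self):
        pts = points_df([("i", "", "w0", "tumor", 0.0, 0.0),
                         ("i", "", "w1", "astrocyte", 1.0, 0.0)])
        with pytest.raises(ValueError):
            cluster_points(pts, radius=20)

    def test_every_point_in_exactly_one_cluster(self):
        rng = np.random.default_rng(0)
        rows = [("i", "", f"w{k % 5}", "tumor",
                 float(rng.uniform(0, 200)), float(rng.uniform(0, 200)))
                for k in range(40)]
        clusters = cluster_points(points_df(rows), radius=15)
        assert sum(c.support for c in clusters) == 40

    def test_row_order_does_not_change_clusters(self):
        rng = np.random.default_rng(3)
        rows = [("i", "", f"w{k % 4}", "tumor",
                 float(rng.uniform(0, 100)), float(rng.uniform(0, 100)))
                for k in range(20)]
        a = cluster_points(points_df(rows), radius=15)
        b = cluster_points(points_df(rows[::-1]), radius=15)
        key = lambda cs: sorted(tuple(np.round(c.centroid, 9)) for c in cs)
        assert key(a) == key(b)


def _partition_cost(xy, groups):
    cost = 0.0
    for g in groups:
        centroid = xy[g].mean(axis=0)
        cost += np.hypot(*(xy[g] - centroid).T).sum()
    return cost


def _feasible(xy, workers, groups, radius):
    for g in groups:
        ws = [workers[i] for i in g]
        if len(set(ws)) != len(ws):
            return False
        centroid = xy[g].mean(axis=0)
        if np.any(np.hypot(*(xy[g] - centroid).T) >= radius):
            return False
    return True


def _all_partitions(items):
    if not items:
        yield []
        return
    head, *rest = items
    for part in _all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [head]] + part[i + 1:]
        yield part + [[head]]


def _maximal(xy, workers, groups, radius):
    """No two clusters of the grouping could still be merged feasibly."""
    for a, b in itertools.combinations(range(len(groups)), 2):
        union = np.concatenate([groups[a], groups[b]])
        if _feasible(xy, workers, [union], radius):
            return False
    return True


def test_greedy_clustering_near_optimal_against_exhaustive_oracle():
    """Greedy agglomeration never beats, and almost always equals, the
    exhaustive minimum total within-cluster distance over all maximal
    feasible groupings (<= 6 points, <= 4 workers).  Maximality matters:
    grouping as much as feasibly possible is what links one cell's clicks
    across workers, and among such groupings smaller spread is better."""
    rng = np.random.default_rng(42)
    radius = 20.0
    equal = 0
    n_instances = 200
    for _ in range(n_instances):
        n = int(rng.integers(2, 7))
        # two cells separated as the scene's hard-core spacing guarantees
        first = rng.uniform(20, 80, size=2)
        angle = rng.uniform(0, 2 * np.pi)
        sep = rng.uniform(50, 80)
        centers = np.stack([first, first + sep * np.array(
            [np.cos(angle), np.sin(angle)])])
        rows = []
        for k in range(n):
            c = centers[k % 2]
            rows.append(("i", "", f"w{k % 4}", "tumor",
                         float(c[0] + rng.normal(0, 6)),
                         float(c[1] + rng.normal(0, 6))))
        pts = points_df(rows)
        xy = pts[["x", "y"]].to_numpy(float)
        workers = pts["worker_id"].to_list()
        clusters = cluster_points(pts, radius=radius)
        greedy_groups = [c.members.index.to_list() for c in clusters]
        greedy_cost = _partition_cost(xy, greedy_groups)
        feasible_parts = [
            [np.array(g) for g in part]
            for part in _all_partitions(list(range(n)))
            if _feasible(xy, workers, [np.array(g) for g in part], radius)]
        best = min(_partition_cost(xy, part) for part in feasible_parts
                   if _maximal(xy, workers, part, radius))
        assert greedy_cost >= best - 1e-9
        if greedy_cost <= best + 1e-9:
            equal += 1
    assert equal / n_instances >= 0.95


class TestMajorityVote:
    def _clusters(self, supports):
        rows = []
        for ci, s in enumerate(supports):
            for w in range(s):
                rows.append(("i", "", f"w{w}", "tumor", 100.0 * ci, 0.0))
        return cluster_points(points_df(rows), radius=20)

    @pytest.mark.parametrize("support,roster,accepted",
                             [(6, 10, True), (5, 10, False), (1, 1, True)])
    def test_strict_majority_rule(self, support, roster, accepted):
        mv = majority_vote(self._clusters([support]), roster)
        assert bool(mv.accepted[0]) is accepted

    def test_inconsistent_roster_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(self._clusters([5]), roster_size=3)

    def test_consensus_at_member_centroid(self):
        pts = points_df([("i", "", "w0", "tumor", 10.0, 0.0),
                         ("i", "", "w1", "tumor", 14.0, 4.0)])
        mv = majority_vote(cluster_points(pts, 20), 2)
        assert (mv.x[0], mv.y[0]) == (12.0, 2.0)


class TestWorkerWeight:
    @pytest.mark.parametrize("wrong,weight", [(0, 1.00), (1, 0.80),
                                              (2, 0.60), (5, 0.05),
                                              (6, 0.05), (20, 0.05)])
    def test_weight_formula(self, wrong, weight):
        gt = gt_points(10, seed=1)
        # build a worker table with `wrong` errors: drop fn cells, add fp
        fn = min(wrong // 2, len(gt))
        fp = wrong - fn
        pred = gt.iloc[fn:][["x", "y"]].copy()
        extra = pd.DataFrame({"x": np.linspace(1000, 2000, fp),
                              "y": np.zeros(fp)})
        pred = pd.concat([pred, extra], ignore_index=True)
        ww = worker_weight(pred, gt, match_radius=5)
        assert ww.wrong_count == wrong
        assert ww.weight == pytest.approx(weight)

    def test_compute_weights_covers_full_roster(self):
        from crowdcell import AnnotationSet
        gt = gt_points(4, seed=2)
        pts = pd.DataFrame({"image_id": "g", "tile_id": "",
                            "worker_id": "a", "class": "tumor",
                            "x": gt.x, "y": gt.y})
        aset = AnnotationSet(points=pts, roster=["a", "b"], frame="image")
        w = compute_weights(aset, gt, match_radius=5)
        assert w["a"].weight == 1.00
        assert w["b"].wrong_count == 4  # all cells missed
        assert w["b"].weight == pytest.approx(0.20)


class TestWeightedVote:
    def _clusters(self, member_workers, x=0.0):
        rows = [("i", "", w, "tumor", x, 0.0) for w in member_workers]
        return cluster_points(points_df(rows), radius=20)

    def test_equal_weights_reduce_to_majority_vote(self):
        roster = [f"w{i}" for i in range(10)]
        weights = {w: 0.7 for w in roster}
        for support in (4, 5, 6, 10):
            clusters = self._clusters(roster[:support])
            mv = majority_vote(clusters, 10)
            wv = weighted_vote(clusters, weights, roster)
            assert mv.accepted.equals(wv.accepted)

    def test_single_reliable_worker_outvotes_floored_crowd(self):
        # weights {1.0} + 9 x 0.05: 1.0 > 0.5 * 1.45
        roster = ["good"] + [f"bad{i}" for i in range(9)]
        weights = {"good": 1.0, **{f"bad{i}": 0.05 for i in range(9)}}
        wv = weighted_vote(self._clusters(["good"]), weights, roster)
        assert bool(wv.accepted[0])
        wv2 = weighted_vote(self._clusters([f"bad{i}" for i in range(9)]),
                            weights, roster)
        assert not bool(wv2.accepted[0])

    def test_empty_cluster_set_gives_empty_output(self):
        assert len(weighted_vote([], {"w0": 1.0}, ["w0"])) == 0

    def test_missing_weight_rejected(self):
        with pytest.raises(KeyError):
            weighted_vote(self._clusters(["w0"]), {}, ["w0"])

    def test_weighted_centroid(self):
        pts = points_df([("i", "", "a", "tumor", 0.0, 0.0),
                         ("i", "", "b", "tumor", 10.0, 0.0)])
        wv = weighted_vote(cluster_points(pts, 20),
                           {"a": 1.0, "b": 0.25}, ["a", "b"])
        assert wv.x[0] == pytest.approx(2.0)  # (0*1 + 10*0.25) / 1.25
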