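"""End-to-end orchestration: simulate -> tile -> annotate -> stitch ->
aggregate -> qc -> boxes -> export -> evaluate.

Every stage reads its inputs from, and writes its artifacts to, a run
directory; a manifest records the configuration, per-stage artifact paths
with checksums, and all derived seeds, so a re-run with the same
configuration reproduces identical CSV and label outputs.

The default configuration encodes the reference study conditions: regions
of 1860 x 1396 px at 0.25 um/px, 30-px tile overlap, a 4 x 4 tile grid for
the tumor task and 2 x 2 for the astrocyte task, a crowd of 10 workers per
task, a hidden ground-truth image per task for worker weighting
(1.00 - 0.20 per wrong cell, floor 0.05), a qualification gate at PPV 0.8,
and detection scoring at confidence 0.25 / IoU 0.35.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import aggregation, boxes as boxes_mod, crowd_sim, detection_eval
from . import quality, scene_sim, tiling
from .crowd_sim import AnnotationSet

logger = logging.getLogger(__name__)

STAGES = ("simulate", "tile", "annotate", "stitch", "aggregate", "qc",
          "boxes", "export", "evaluate")

TASKS = ("tumor", "astrocyte")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "runs/demo",
    "variant": "Var1",
    "scene": {
        "width": 1860, "height": 1396, "pixel_size": 0.25,
        "densities": dict(scene_sim.DEFAULT_DENSITIES),
        "min_spacing": 40.0, "background_level": 0.05, "noise_sd": 0.02,
    },
    "images": {"n_tumor": 1, "n_astrocyte": 1},
    "gt_image": {"tumor": {"width": 518, "height": 438},
                 "astrocyte": {"width": 940, "height": 878}},
    "tiling": {"tumor_grid": [4, 4], "astrocyte_grid": [2, 2],
               "overlap": 30, "dedup_radius": 5.0},
    "crowd": {"n_workers": 10, "sensitivity_range": [0.5, 0.95],
              "fp_range": [0.0, 3.0], "localization_sd": 3.0,
              "astro_confusion": [0.1, 0.4]},
    "aggregation": {"cluster_radius": 20.0, "match_radius": 20.0},
    "quality": {"match_radius": 20.0, "min_ppv": 0.8},
    "boxes": {"color_tolerance": 0.25, "max_radius": 60.0,
              "fill_channel": "GFAP"},
    "eval": {"confidence_min": 0.25, "iou_min": 0.35},
}


def _deep_update(base: dict, overrides: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in overrides.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None, overrides: Mapping | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and explicit keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _deep_update(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_update(cfg, overrides)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, label: str) -> int:
    return crowd_sim.worker_seed(master, f"stage:{label}")


def _image_registry(outdir: Path) -> pd.DataFrame:
    path = outdir / "images.csv"
    if not path.exists():
        raise FileNotFoundError(
            "missing images.csv; run the 'simulate' stage first")
    return pd.read_csv(path, dtype={"image_id": str, "task": str})


class PipelineRun:
    """Stateful runner bound to one output directory and configuration."""

    def __init__(self, config: Mapping, outdir=None):
        self.config = copy.deepcopy(dict(config))
        self.outdir = Path(outdir if outdir is not None
                           else self.config["outdir"])
        self.seed = int(self.config["seed"])
        self.artifacts: dict[str, list[str]] = {}

    # -- helpers ---------------------------------------------------------

    def _record(self, stage: str, path: Path) -> None:
        self.artifacts.setdefault(stage, []).append(
            str(path.relative_to(self.outdir)))

    def _dir(self, name: str) -> Path:
        d = self.outdir / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _scene_config(self, task: str, gt_image: bool) -> scene_sim.SceneConfig:
        sc = self.config["scene"]
        densities = dict(sc["densities"])
        if gt_image:
            size = self.config["gt_image"][task]
            width, height = size["width"], size["height"]
        else:
            width, height = sc["width"], sc["height"]
        return scene_sim.SceneConfig(
            width=width, height=height, pixel_size=sc["pixel_size"],
            densities=densities, min_spacing=sc["min_spacing"],
            background_level=sc["background_level"], noise_sd=sc["noise_sd"])

    def _image_ids(self) -> pd.DataFrame:
        return _image_registry(self.outdir)

    def _profiles(self, task: str) -> list[crowd_sim.WorkerProfile]:
        cc = self.config["crowd"]
        confusion = None
        if task == "astrocyte" and cc.get("astro_confusion"):
            lo, hi = cc["astro_confusion"]
            confusion = {("neuron", "astrocyte"): (lo, hi)}
        return crowd_sim.sample_profiles(
            int(cc["n_workers"]), seed=_stage_seed(self.seed, f"crowd:{task}"),
            target_class=task,
            sensitivity_range=tuple(cc["sensitivity_range"]),
            fp_range=tuple(cc["fp_range"]),
            localization_sd=cc["localization_sd"],
            confusion=confusion)

    def _plan(self, task: str, width: int, height: int) -> tiling.TilePlan:
        tc = self.config["tiling"]
        grid = tuple(tc["tumor_grid"] if task == "tumor"
                     else tc["astrocyte_grid"])
        return tiling.plan_tiles(width, height, grid, tc["overlap"])

    # -- stages ----------------------------------------------------------

    def simulate(self) -> None:
        """Scenes, channel stacks, RGB renders and ground truth."""
        d = self._dir("scenes")
        variant = scene_sim.variant_registry()[self.config["variant"]]
        rows = []
        for task in TASKS:
            n = int(self.config["images"][f"n_{task}"])
            ids = [f"{task}{i:02d}" for i in range(n)] + [f"{task}_gtimg"]
            for image_id in ids:
                is_gt = image_id.endswith("_gtimg")
                cfg = self._scene_config(task, gt_image=is_gt)
                seed = _stage_seed(self.seed, f"scene:{image_id}")
                scene = scene_sim.make_scene(cfg, seed)
                stack = scene_sim.render_channels(scene)
                scene_sim.write_channel_stack(d / f"{image_id}.tif", stack)
                scene_sim.ground_truth(scene).to_csv(
                    d / f"{image_id}_gt.csv", index=False)
                scene_sim.write_rgb_png(
                    d / f"{image_id}_{variant.variant_id}.png",
                    scene_sim.render_variant(stack, variant))
                for suffix in (".tif", "_gt.csv",
                               f"_{variant.variant_id}.png"):
                    self._record("simulate", d / f"{image_id}{suffix}")
                rows.append({"image_id": image_id, "task": task,
                             "width": cfg.width, "height": cfg.height,
                             "seed": seed, "gt_image": is_gt})
        reg = pd.DataFrame(rows)
        reg.to_csv(self.outdir / "images.csv", index=False)
        self._record("simulate", self.outdir / "images.csv")

    def tile(self) -> None:
        """Tile plans and per-tile RGB crops (the annotation material)."""
        d = self._dir("tiles")
        variant_id = self.config["variant"]
        for _, img in self._image_ids().iterrows():
            if img["gt_image"]:
                continue  # shown whole, as the final task item
            plan = self._plan(img["task"], img["width"], img["height"])
            plan.to_csv(d / f"{img['image_id']}_plan.csv")
            self._record("tile", d / f"{img['image_id']}_plan.csv")
            rgb = scene_sim.read_rgb_png(
                self.outdir / "scenes" / f"{img['image_id']}_{variant_id}.png")
            for tid, crop in tiling.crop_tiles(rgb, plan).items():
                path = d / f"{img['image_id']}_{tid}.png"
                scene_sim.write_rgb_png(path, crop)
                self._record("tile", path)

    def _simulate_task_annotations(self, task: str, target_class: str,
                                   suffix: str, stage: str) -> None:
        d = self._dir("annotations")
        profiles = ([p for p in self._profiles(task)] if target_class == task
                    else [crowd_sim.WorkerProfile(
                        worker_id=p.worker_id, sensitivity={
                            target_class: p.sensitivity.get(task, 0.7)},
                        fp_rate=p.fp_rate,
                        localization_sd=p.localization_sd,
                        fp_class=target_class)
                        for p in self._profiles(task)])
        reg = self._image_ids()
        for _, img in reg[reg["task"] == task].iterrows():
            image_id = img["image_id"]
            gt = pd.read_csv(self.outdir / "scenes" / f"{image_id}_gt.csv")
            seed = _stage_seed(self.seed, f"annotate:{image_id}:{suffix}")
            if img["gt_image"]:
                bounds = (0.0, 0.0, float(img["width"]), float(img["height"]))
                annos = crowd_sim.simulate_crowd(
                    gt.rename(columns={"class": "class"}), bounds,
                    profiles=profiles, seed=seed, image_id=image_id,
                    target_class=target_class)
            else:
                plan = tiling.TilePlan.from_csv(
                    self.outdir / "tiles" / f"{image_id}_plan.csv",
                    int(img["width"]), int(img["height"]),
                    overlap=self.config["tiling"]["overlap"])
                frames = []
                for tid, x0, y0, x1, y1 in plan.tiles:
                    in_tile = gt[(gt["x"] >= x0) & (gt["x"] < x1)
                                 & (gt["y"] >= y0) & (gt["y"] < y1)].copy()
                    in_tile["x"] -= x0
                    in_tile["y"] -= y0
                    tile_set = crowd_sim.simulate_crowd(
                        in_tile, (0.0, 0.0, float(x1 - x0), float(y1 - y0)),
                        profiles=profiles,
                        seed=crowd_sim.worker_seed(seed, tid),
                        image_id=image_id, tile_id=tid,
                        target_class=target_class)
                    frames.append(tile_set.points)
                annos = AnnotationSet(
                    points=pd.concat(frames, ignore_index=True),
                    roster=sorted(p.worker_id for p in profiles),
                    frame="tile")
            annos.to_csv(d / f"{image_id}{suffix}.csv",
                         d / f"{image_id}{suffix}_roster.csv")
            self._record(stage, d / f"{image_id}{suffix}.csv")
            self._record(stage, d / f"{image_id}{suffix}_roster.csv")

    def annotate(self) -> None:
        """Simulated crowds click on the task class of every tile, and on
        the hidden ground-truth image; a second crowd provides cross-class
        annotations used later for label consolidation."""
        for task in TASKS:
            self._simulate_task_annotations(task, task, "", "annotate")
            other = "astrocyte" if task == "tumor" else "tumor"
            self._simulate_task_annotations(task, other, "_cross", "annotate")

    def stitch(self) -> None:
        """Per-tile annotations back to image coordinates, de-duplicated."""
        d = self._dir("stitched")
        dedup = self.config["tiling"]["dedup_radius"]
        for _, img in self._image_ids().iterrows():
            image_id = img["image_id"]
            for suffix in ("", "_cross"):
                src = self.outdir / "annotations" / f"{image_id}{suffix}.csv"
                annos = AnnotationSet.from_csv(
                    src, self.outdir / "annotations"
                    / f"{image_id}{suffix}_roster.csv")
                if img["gt_image"]:
                    stitched = AnnotationSet(points=annos.points,
                                             roster=annos.roster,
                                             frame="image")
                else:
                    plan = tiling.TilePlan.from_csv(
                        self.outdir / "tiles" / f"{image_id}_plan.csv",
                        int(img["width"]), int(img["height"]),
                        overlap=self.config["tiling"]["overlap"])
                    stitched = tiling.stitch_points(annos, plan,
                                                    dedup_radius=dedup)
                stitched.to_csv(d / f"{image_id}{suffix}.csv",
                                d / f"{image_id}{suffix}_roster.csv")
                self._record("stitch", d / f"{image_id}{suffix}.csv")
                self._record("stitch", d / f"{image_id}{suffix}_roster.csv")

    def _consensus_for(self, image_id: str, target_class: str,
                       suffix: str = "") -> tuple[pd.DataFrame, pd.DataFrame]:
        """MV and WV consensus tables for one stitched annotation set."""
        ac = self.config["aggregation"]
        annos = AnnotationSet.from_csv(
            self.outdir / "stitched" / f"{image_id}{suffix}.csv",
            self.outdir / "stitched" / f"{image_id}{suffix}_roster.csv",
            frame="image")
        pts = annos.points[annos.points["class"] == target_class]
        clusters = aggregation.cluster_points(pts, ac["cluster_radius"]) \
            if len(pts) else []
        mv = aggregation.majority_vote(clusters, len(annos.roster))
        task = target_class if not suffix else \
            ("astrocyte" if target_class == "tumor" else "tumor")
        weights = self._task_weights(task if not suffix else task,
                                    target_class, suffix)
        wv = aggregation.weighted_vote(clusters, weights, annos.roster)
        return mv, wv

    def _task_weights(self, task: str, target_class: str,
                      suffix: str) -> dict[str, aggregation.WorkerWeight]:
        gt_id = f"{task}_gtimg"
        annos = AnnotationSet.from_csv(
            self.outdir / "stitched" / f"{gt_id}{suffix}.csv",
            self.outdir / "stitched" / f"{gt_id}{suffix}_roster.csv",
            frame="image")
        gt = pd.read_csv(self.outdir / "scenes" / f"{gt_id}_gt.csv")
        gt_target = gt[gt["class"] == target_class]
        pts = annos.points[annos.points["class"] == target_class]
        return aggregation.compute_weights(
            AnnotationSet(points=pts, roster=annos.roster, frame="image"),
            gt_target, self.config["aggregation"]["match_radius"])

    def aggregate(self) -> None:
        """Cluster stitched points; write MV/WV consensus and weights."""
        d = self._dir("consensus")
        reg = self._image_ids()
        for task in TASKS:
            weights = self._task_weights(task, task, "")
            aggregation.weights_frame(weights).to_csv(
                d / f"weights_{task}.csv", index=False)
            self._record("aggregate", d / f"weights_{task}.csv")
        for _, img in reg.iterrows():
            image_id, task = img["image_id"], img["task"]
            for suffix, cls in (("", task),
                                ("_cross",
                                 "astrocyte" if task == "tumor" else "tumor")):
                mv, wv = self._consensus_for(image_id, cls, suffix)
                mv.to_csv(d / f"{image_id}{suffix}_mv.csv", index=False)
                wv.to_csv(d / f"{image_id}{suffix}_wv.csv", index=False)
                self._record("aggregate", d / f"{image_id}{suffix}_mv.csv")
                self._record("aggregate", d / f"{image_id}{suffix}_wv.csv")

    def qc(self) -> None:
        """Consensus and individual quality vs ground truth; Fleiss' kappa
        on the hidden ground-truth image."""
        d = self._dir("qc")
        qcfg = self.config["quality"]
        radius = qcfg["match_radius"]
        out: dict = {}
        for task in TASKS:
            gt_id = f"{task}_gtimg"
            gt = pd.read_csv(self.outdir / "scenes" / f"{gt_id}_gt.csv")
            gt_t = gt[gt["class"] == task]
            annos = AnnotationSet.from_csv(
                self.outdir / "stitched" / f"{gt_id}.csv",
                self.outdir / "stitched" / f"{gt_id}_roster.csv",
                frame="image")
            pts = annos.points[annos.points["class"] == task]
            individual_f1 = []
            for w in annos.roster:
                rep = quality.prf(quality.match_to_truth(
                    pts[pts["worker_id"] == w], gt_t, radius))
                individual_f1.append(rep.f1)
            table = quality.build_rating_items(
                AnnotationSet(points=pts, roster=annos.roster, frame="image"),
                gt_t, radius)
            kappa = quality.fleiss_kappa(table)
            task_out = {"median_individual_f1": float(np.median(individual_f1)),
                        "fleiss_kappa": float(kappa), "n_cells": int(len(gt_t))}
            for rule in ("mv", "wv"):
                cons = pd.read_csv(
                    self.outdir / "consensus" / f"{gt_id}_{rule}.csv")
                acc = cons[cons["accepted"]]
                rep = quality.prf(quality.match_to_truth(acc, gt_t, radius))
                task_out[rule] = {"tpr": rep.tpr, "ppv": rep.ppv, "f1": rep.f1}
            out[task] = task_out
            logger.info("qc[%s]: kappa=%.3f mv_f1=%.3f", task, kappa,
                        task_out["mv"]["f1"])
        (d / "qc.json").write_text(json.dumps(out, indent=2))
        self._record("qc", d / "qc.json")

    def _cross_detector(self):
        """Default consolidation detector: the aggregation + flood-fill
        pipeline run on the image's cross-class crowd annotations."""
        def detect(ls: boxes_mod.LabelSet, missing: str):
            cons = pd.read_csv(
                self.outdir / "consensus" / f"{ls.image_id}_cross_mv.csv")
            cons = cons[cons["class"] == missing]
            if not len(cons):
                return []
            return self._fill_boxes(ls.image_id, cons).boxes
        return detect

    def _fill_boxes(self, image_id: str,
                    consensus: pd.DataFrame) -> boxes_mod.LabelSet:
        bc = self.config["boxes"]
        stack = scene_sim.read_channel_stack(
            self.outdir / "scenes" / f"{image_id}.tif")
        plane = stack.channels[bc["fill_channel"]]
        roster = int(self.config["crowd"]["n_workers"])
        return boxes_mod.boxes_from_consensus(
            plane, consensus, image_id, roster,
            color_tolerance=bc["color_tolerance"],
            max_radius=bc["max_radius"])

    def boxes(self) -> None:
        """Flood-fill MV consensus points into boxes and consolidate the
        two single-class pools into two-class label sets."""
        d = self._dir("labels")
        reg = self._image_ids()
        pools: dict[str, list[boxes_mod.LabelSet]] = {t: [] for t in TASKS}
        for _, img in reg.iterrows():
            if img["gt_image"]:
                continue
            cons = pd.read_csv(self.outdir / "consensus"
                               / f"{img['image_id']}_mv.csv")
            pools[img["task"]].append(
                self._fill_boxes(img["image_id"], cons))
        consolidated = boxes_mod.consolidate_labels(
            pools["astrocyte"], pools["tumor"], self._cross_detector())
        for ls in consolidated:
            rows = [{"image_id": ls.image_id, "class": b.cell_class,
                     "x_min": b.x_min, "y_min": b.y_min, "x_max": b.x_max,
                     "y_max": b.y_max, "confidence": b.confidence}
                    for b in ls.boxes]
            pd.DataFrame(rows, columns=["image_id", "class", "x_min", "y_min",
                                        "x_max", "y_max", "confidence"]) \
                .to_csv(d / f"{ls.image_id}_boxes.csv", index=False)
            self._record("boxes", d / f"{ls.image_id}_boxes.csv")

    def _load_labelsets(self) -> list[boxes_mod.LabelSet]:
        reg = self._image_ids()
        out = []
        for _, img in reg.iterrows():
            if img["gt_image"]:
                continue
            df = pd.read_csv(self.outdir / "labels"
                             / f"{img['image_id']}_boxes.csv")
            bxs = [boxes_mod.BBox(
                cell_class=r["class"], x_min=r["x_min"], y_min=r["y_min"],
                x_max=r["x_max"], y_max=r["y_max"],
                confidence=None if pd.isna(r["confidence"])
                else float(r["confidence"]))
                for _, r in df.iterrows()]
            out.append(boxes_mod.LabelSet(
                image_id=img["image_id"], width=int(img["width"]),
                height=int(img["height"]), boxes=bxs))
        return out

    def export(self) -> None:
        """Detector-ready YOLO txt labels plus a COCO JSON."""
        d = self._dir("labels")
        label_sets = self._load_labelsets()
        for ls in label_sets:
            path = d / f"{ls.image_id}.txt"
            path.write_text(boxes_mod.export_yolo(ls))
            self._record("export", path)
        classes = sorted(boxes_mod.DEFAULT_CLASS_INDEX,
                         key=boxes_mod.DEFAULT_CLASS_INDEX.get)
        (d / "classes.txt").write_text("\n".join(classes) + "\n")
        self._record("export", d / "classes.txt")
        (d / "coco.json").write_text(
            json.dumps(boxes_mod.export_coco(label_sets), indent=2))
        self._record("export", d / "coco.json")

    def evaluate(self) -> None:
        """Score the consolidated crowd-derived boxes against scene truth."""
        d = self._dir("eval")
        ec = self.config["eval"]
        config = detection_eval.EvalConfig(confidence_min=ec["confidence_min"],
                                           iou_min=ec["iou_min"])
        preds = {ls.image_id: ls.boxes for ls in self._load_labelsets()}
        reg = self._image_ids()
        gts = {}
        for _, img in reg.iterrows():
            if img["gt_image"]:
                continue
            gt = pd.read_csv(self.outdir / "scenes"
                             / f"{img['image_id']}_gt.csv")
            gts[img["image_id"]] = boxes_mod.gt_boxes_from_frame(
                gt, img["image_id"], int(img["width"]), int(img["height"]),
                classes=TASKS).boxes
        report = detection_eval.evaluate_suite(preds, gts, config)
        (d / "eval.json").write_text(json.dumps(
            {"per_class": report.per_class, "mean": report.mean}, indent=2))
        self._record("evaluate", d / "eval.json")

    # -- driver ----------------------------------------------------------

    def run(self, stages: Sequence[str] | None = None) -> dict:
        requested = list(STAGES) if stages is None or "all" in stages \
            else list(stages)
        for s in requested:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
        ordered = [s for s in STAGES if s in requested]
        self.outdir.mkdir(parents=True, exist_ok=True)
        for stage in ordered:
            logger.info("running stage %s", stage)
            getattr(self, stage)()
        manifest = {
            "config": self.config,
            "seed": self.seed,
            "stages": ordered,
            "artifacts": {
                stage: [{"path": p, "sha256": _sha256(self.outdir / p)}
                        for p in paths]
                for stage, paths in self.artifacts.items()},
        }
        (self.outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=float))
        return manifest


def run_pipeline(config: Mapping, stages: Sequence[str] | None = None,
                 outdir=None) -> dict:
    """Execute the requested stages in dependency order; returns the
    manifest (also written to ``<outdir>/manifest.json``)."""
    return PipelineRun(config, outdir=outdir).run(stages)
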