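"""Point-to-box conversion and detector-ready label export.

Consensus points mark cell nuclei; to train a box detector the cell outline
is recovered in two steps: (1) the image background is removed with a
threshold placed at the first valley of the intensity histogram above the
dominant background mode, and (2) a seeded 4-connected flood fill grows from
the consensus point, accepting neighbors that are above background, close in
color to the running region mean, and within a radius bound.  The tight
bounds of the filled mask become the bounding box.

Because astrocytes and tumor cells are annotated on different images, the
two single-class label sets are consolidated: a pluggable single-class
detector supplies the missing class for every image, and overlapping boxes
are resolved by confidence.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from skimage.filters import threshold_otsu

DEFAULT_COLOR_TOLERANCE = 0.25
DEFAULT_MAX_RADIUS = 60.0  # px; generous cytoplasm bound at 0.25 um/px


@dataclass(frozen=True)
class BBox:
    """Axis-aligned half-open box with class and optional confidence."""

    cell_class: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("box must have positive width and height")
        if self.confidence is not None and not 0 <= self.confidence <= 1:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass
class LabelSet:
    """Consolidated per-image labels for detector training."""

    image_id: str
    width: int
    height: int
    boxes: list[BBox] = field(default_factory=list)


@dataclass
class BackgroundThreshold:
    threshold: float
    fallback: bool = False  # True when Otsu had to stand in


@dataclass
class CellMask:
    """Flood-fill segmentation result: 4-connected pixels around a seed."""

    seed: tuple[int, int]
    pixels: np.ndarray  # (n, 2) integer (x, y)
    connected: bool = True
    seed_on_background: bool = False

    def __post_init__(self) -> None:
        if len(self.pixels) < 1:
            raise ValueError("mask must contain at least one pixel")


def estimate_background_threshold(plane: np.ndarray, bins: int = 256,
                                  smooth_sigma: float = 2.0
                                  ) -> BackgroundThreshold:
    """Threshold separating background from stained pixels.

    The intensity histogram is smoothed; the threshold is the first local
    minimum above the dominant low-intensity mode that genuinely separates
    two modes (the valley must lie below half the height of the smoothed
    histogram on either side, so sampling wiggles in a unimodal histogram
    are not mistaken for valleys).  When no such minimum exists the Otsu
    threshold is used and flagged as a fallback.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.size == 0 or np.ptp(plane) == 0:
        raise ValueError("plane is constant; no histogram structure")
    hist, edges = np.histogram(plane.ravel(), bins=bins)
    smooth = gaussian_filter1d(hist.astype(float), smooth_sigma)
    centers = (edges[:-1] + edges[1:]) / 2
    # Dominant low-intensity mode: highest peak in the lower half of the
    # smoothed histogram (background dominates mIF images).
    lower = smooth[: bins // 2]
    mode = int(np.argmax(lower)) if lower.size else int(np.argmax(smooth))
    floor = 0.05 * smooth.max()  # a real second mode, not tail noise
    for i in range(mode + 1, bins - 1):
        if (smooth[i] <= smooth[i - 1] and smooth[i] < smooth[i + 1]
                and smooth[i] <= 0.5 * smooth[: i + 1].max()
                and smooth[i] <= 0.5 * smooth[i + 1:].max()
                and smooth[i + 1:].max() >= floor):
            return BackgroundThreshold(threshold=float(centers[i]))
    return BackgroundThreshold(threshold=float(threshold_otsu(plane)),
                               fallback=True)


def flood_fill_cell(image: np.ndarray, seed: tuple[float, float],
                    color_tolerance: float = DEFAULT_COLOR_TOLERANCE,
                    background_threshold: float | Sequence[float] = 0.0,
                    max_radius: float = DEFAULT_MAX_RADIUS) -> CellMask:
    """Grow a cell mask from a seed point by breadth-first flood fill.

    ``image`` is a 2-D intensity plane or an (H, W, C) stack of the
    class-relevant channels.  A 4-connected neighbor (visited in fixed
    N, E, S, W order) is included iff (a) any channel exceeds its background
    threshold, (b) its Euclidean color distance to the running region mean
    is at most ``color_tolerance``, and (c) it lies within ``max_radius`` of
    the seed.  The region mean is updated incrementally, so the procedure is
    deterministic.  A seed on background yields the minimal mask {seed},
    flagged.
    """
    if color_tolerance < 0 or max_radius < 0:
        raise ValueError("parameters must be non-negative")
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
    h, w, c = img.shape
    thr = np.broadcast_to(np.asarray(background_threshold, dtype=float), (c,))
    sx, sy = int(round(seed[0])), int(round(seed[1]))
    if not (0 <= sx < w and 0 <= sy < h):
        raise ValueError("seed outside image")

    def foreground(x: int, y: int) -> bool:
        return bool(np.any(img[y, x] > thr))

    if not foreground(sx, sy):
        return CellMask(seed=(sx, sy), pixels=np.array([[sx, sy]]),
                        seed_on_background=True)

    visited = np.zeros((h, w), dtype=bool)
    visited[sy, sx] = True
    pixels = [(sx, sy)]
    mean = img[sy, sx].astype(float).copy()
    queue = deque([(sx, sy)])
    r2 = max_radius ** 2
    while queue:
        x, y = queue.popleft()
        for dx, dy in ((0, -1), (1, 0), (0, 1), (-1, 0)):  # N, E, S, W
            nx, ny = x + dx, y + dy
            if not (0 <= nx < w and 0 <= ny < h) or visited[ny, nx]:
                continue
            visited[ny, nx] = True
            if (nx - sx) ** 2 + (ny - sy) ** 2 > r2:
                continue
            if not foreground(nx, ny):
                continue
            if np.linalg.norm(img[ny, nx] - mean) > color_tolerance:
                continue
            pixels.append((nx, ny))
            mean += (img[ny, nx] - mean) / len(pixels)
            queue.append((nx, ny))
    return CellMask(seed=(sx, sy), pixels=np.array(pixels, dtype=int))


def mask_to_bbox(mask: CellMask, cell_class: str,
                 confidence: float | None = None) -> BBox:
    """Tight half-open bounding box of a mask."""
    xs = mask.pixels[:, 0]
    ys = mask.pixels[:, 1]
    return BBox(cell_class=cell_class,
                x_min=float(xs.min()), y_min=float(ys.min()),
                x_max=float(xs.max() + 1), y_max=float(ys.max() + 1),
                confidence=confidence)


def boxes_from_consensus(plane: np.ndarray, consensus: pd.DataFrame,
                         image_id: str, roster_size: int,
                         color_tolerance: float = DEFAULT_COLOR_TOLERANCE,
                         max_radius: float = DEFAULT_MAX_RADIUS,
                         background: BackgroundThreshold | None = None
                         ) -> LabelSet:
    """Flood-fill every accepted consensus point of one image into a box.

    ``plane`` is the channel (or channel stack) the cell outline is read
    from — by default the pipeline uses the cytoplasmic marker (GFAP) plane,
    which delineates the astrocyte/tumor footprint.  Box confidence is the
    normalized vote support.
    """
    plane = np.asarray(plane, dtype=float)
    h, w = plane.shape[:2]
    if background is None:
        background = estimate_background_threshold(plane if plane.ndim == 2
                                                   else plane.mean(axis=2))
    boxes = []
    for _, row in consensus.iterrows():
        if "accepted" in consensus.columns and not row["accepted"]:
            continue
        mask = flood_fill_cell(plane, (row["x"], row["y"]),
                               color_tolerance=color_tolerance,
                               background_threshold=background.threshold,
                               max_radius=max_radius)
        conf = None
        if roster_size > 0 and "support" in consensus.columns:
            conf = min(1.0, float(row["support"]) / roster_size)
        boxes.append(mask_to_bbox(mask, row["class"], confidence=conf))
    return LabelSet(image_id=image_id, width=w, height=h, boxes=boxes)


def _iou(a: BBox, b: BBox) -> float:
    from .detection_eval import iou
    return iou(a, b)


def consolidate_labels(astro_labels: Sequence[LabelSet],
                       tumor_labels: Sequence[LabelSet],
                       cross_detector: Callable[[LabelSet, str], Sequence[BBox]],
                       iou_overlap: float = 0.5) -> list[LabelSet]:
    """Merge the two single-class label pools into two-class label sets.

    The pools must reference disjoint images (the two annotation tasks used
    different images).  For every image the missing class is supplied by
    ``cross_detector(labelset, missing_class)``; where boxes overlap with
    IoU > ``iou_overlap`` the higher-confidence box survives (a box without
    confidence is treated as certain).
    """
    astro_ids = {ls.image_id for ls in astro_labels}
    tumor_ids = {ls.image_id for ls in tumor_labels}
    shared = astro_ids & tumor_ids
    if shared:
        raise ValueError(f"images present in both pools: {sorted(shared)}")

    out = []
    for pool, missing in ((astro_labels, "tumor"), (tumor_labels, "astrocyte")):
        for ls in pool:
            extra = list(cross_detector(ls, missing))
            merged = list(ls.boxes) + extra
            merged.sort(key=lambda b: (-(b.confidence
                                         if b.confidence is not None else 1.0),
                                       b.x_min, b.y_min))
            kept: list[BBox] = []
            for box in merged:
                if any(_iou(box, k) > iou_overlap for k in kept):
                    continue
                kept.append(box)
            out.append(LabelSet(image_id=ls.image_id, width=ls.width,
                                height=ls.height, boxes=kept))
    return out


DEFAULT_CLASS_INDEX = {"astrocyte": 0, "tumor": 1}


def export_yolo(labels: LabelSet,
                class_index: Mapping[str, int] = DEFAULT_CLASS_INDEX) -> str:
    """One line per box: ``class x_center y_center width height`` with
    coordinates normalized to [0, 1] at six decimal places."""
    lines = []
    for b in labels.boxes:
        if not (0 <= b.x_min and b.x_max <= labels.width
                and 0 <= b.y_min and b.y_max <= labels.height):
            raise ValueError(f"box {b} outside image {labels.image_id!r}")
        cx = (b.x_min + b.x_max) / 2 / labels.width
        cy = (b.y_min + b.y_max) / 2 / labels.height
        bw = (b.x_max - b.x_min) / labels.width
        bh = (b.y_max - b.y_min) / labels.height
        lines.append(f"{class_index[b.cell_class]} "
                     f"{cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    return "\n".join(lines) + ("\n" if lines else "")


def import_yolo(text: str, image_id: str, width: int, height: int,
                class_index: Mapping[str, int] = DEFAULT_CLASS_INDEX
                ) -> LabelSet:
    index_class = {v: k for k, v in class_index.items()}
    boxes = []
    for line in text.splitlines():
        if not line.strip():
            continue
        ci, cx, cy, bw, bh = line.split()
        cx, cy, bw, bh = map(float, (cx, cy, bw, bh))
        boxes.append(BBox(cell_class=index_class[int(ci)],
                          x_min=(cx - bw / 2) * width,
                          y_min=(cy - bh / 2) * height,
                          x_max=(cx + bw / 2) * width,
                          y_max=(cy + bh / 2) * height))
    return LabelSet(image_id=image_id, width=width, height=height, boxes=boxes)


def export_coco(label_sets: Sequence[LabelSet],
                class_index: Mapping[str, int] = DEFAULT_CLASS_INDEX) -> dict:
    """COCO-style dict (images / annotations / categories) for interchange."""
    images, annotations = [], []
    ann_id = 1
    for img_id_num, ls in enumerate(label_sets, start=1):
        images.append({"id": img_id_num, "file_name": f"{ls.image_id}.png",
                       "width": ls.width, "height": ls.height})
        for b in ls.boxes:
            annotations.append({
                "id": ann_id, "image_id": img_id_num,
                "category_id": class_index[b.cell_class],
                "bbox": [b.x_min, b.y_min, b.x_max - b.x_min,
                         b.y_max - b.y_min],
                "area": b.area, "iscrowd": 0,
                **({"score": b.confidence} if b.confidence is not None else {}),
            })
            ann_id += 1
    categories = [{"id": v, "name": k}
                  for k, v in sorted(class_index.items(), key=lambda kv: kv[1])]
    return {"images": images, "annotations": annotations,
            "categories": categories}


def gt_boxes_from_frame(gt: pd.DataFrame, image_id: str, width: int,
                        height: int,
                        classes: Iterable[str] | None = None) -> LabelSet:
    """Ground-truth LabelSet from a scene ground-truth table."""
    boxes = []
    for _, row in gt.iterrows():
        if classes is not None and row["class"] not in classes:
            continue
        boxes.append(BBox(cell_class=row["class"],
                          x_min=float(max(0, row["x_min"])),
                          y_min=float(max(0, row["y_min"])),
                          x_max=float(min(width, row["x_max"])),
                          y_max=float(min(height, row["y_max"]))))
    return LabelSet(image_id=image_id, width=width, height=height, boxes=boxes)
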