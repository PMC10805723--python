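"""Overlapping tiling of annotation images and stitching of point labels.

Large regions are cut into a grid of tiles sharing a fixed pixel overlap
(default 30 px) so that cells sitting on an internal boundary are shown in
full in at least one tile.  After annotation, per-tile points are translated
back to the image frame; clicks the same worker placed on the same cell in
two overlapping tiles are merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .crowd_sim import POINT_COLUMNS, AnnotationSet
from .scene_sim import ChannelStack

DEFAULT_OVERLAP = 30
DEFAULT_DEDUP_RADIUS = 5.0


@dataclass
class TilePlan:
    """Row-major half-open tile rectangles covering an image exactly."""

    width: int
    height: int
    grid: tuple[int, int]
    overlap: int
    tiles: list[tuple[str, int, int, int, int]]

    def bounds(self, tile_id: str) -> tuple[int, int, int, int]:
        for tid, x0, y0, x1, y1 in self.tiles:
            if tid == tile_id:
                return x0, y0, x1, y1
        raise KeyError(f"unknown tile {tile_id!r}")

    def tiles_containing(self, x: float, y: float) -> list[str]:
        return [tid for tid, x0, y0, x1, y1 in self.tiles
                if x0 <= x < x1 and y0 <= y < y1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tiles,
                            columns=["tile_id", "x0", "y0", "x1", "y1"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, width: int, height: int,
                 grid: tuple[int, int] | None = None,
                 overlap: int = DEFAULT_OVERLAP) -> "TilePlan":
        df = pd.read_csv(path, dtype={"tile_id": str})
        tiles = [tuple(r) for r in df.itertuples(index=False)]
        gx = len({t[1] for t in tiles})
        gy = len({t[2] for t in tiles})
        return cls(width=width, height=height, grid=grid or (gx, gy),
                   overlap=overlap, tiles=tiles)


def _starts(extent: int, n: int, tile: int) -> list[int]:
    if n == 1:
        return [0]
    return [min(max(0, round(i * (extent - tile) / (n - 1))), extent - tile)
            for i in range(n)]


def plan_tiles(width: int, height: int, grid: tuple[int, int],
               overlap: int = DEFAULT_OVERLAP) -> TilePlan:
    """Plan a ``gx x gy`` grid of equal-sized tiles with >= ``overlap``
    shared pixels between adjacent tiles.

    Tile width is ``ceil((width + (gx-1)*overlap) / gx)`` with x-starts at
    ``round(i * (width - tile_width) / (gx - 1))`` (clamped), analogously in
    y.  The union of tiles covers the image exactly.
    """
    gx, gy = grid
    if gx < 1 or gy < 1:
        raise ValueError("grid counts must be >= 1")
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    tile_w = math.ceil((width + (gx - 1) * overlap) / gx)
    tile_h = math.ceil((height + (gy - 1) * overlap) / gy)
    if tile_w > width or tile_h > height:
        raise ValueError("overlap too large for this grid and image")
    xs = _starts(width, gx, tile_w)
    ys = _starts(height, gy, tile_h)
    tiles = []
    for iy, y0 in enumerate(ys):
        for ix, x0 in enumerate(xs):
            tiles.append((f"r{iy}c{ix}", x0, y0, x0 + tile_w, y0 + tile_h))
    return TilePlan(width=width, height=height, grid=(gx, gy),
                    overlap=overlap, tiles=tiles)


def crop_tiles(image, plan: TilePlan) -> dict[str, object]:
    """Pixel-exact half-open crops of an array or ChannelStack per tile."""
    if isinstance(image, ChannelStack):
        h, w = image.shape
    else:
        image = np.asarray(image)
        h, w = image.shape[:2]
    if (h, w) != (plan.height, plan.width):
        raise ValueError(f"image shape {(h, w)} does not match plan "
                         f"{(plan.height, plan.width)}")
    out: dict[str, object] = {}
    for tid, x0, y0, x1, y1 in plan.tiles:
        if isinstance(image, ChannelStack):
            out[tid] = ChannelStack(channels={
                name: plane[y0:y1, x0:x1].copy()
                for name, plane in image.channels.items()})
        else:
            out[tid] = image[y0:y1, x0:x1].copy()
    return out


def crop_points(points: pd.DataFrame, plan: TilePlan) -> pd.DataFrame:
    """Assign image-frame points to every tile containing them, translated
    to tile-frame coordinates (a point in an overlap appears in each tile)."""
    rows = []
    for _, p in points.iterrows():
        for tid in plan.tiles_containing(p["x"], p["y"]):
            x0, y0, _, _ = plan.bounds(tid)
            row = dict(p)
            row["tile_id"] = tid
            row["x"] = p["x"] - x0
            row["y"] = p["y"] - y0
            rows.append(row)
    cols = list(points.columns)
    if "tile_id" not in cols:
        cols.append("tile_id")
    return pd.DataFrame(rows, columns=cols)


def stitch_points(annotations: AnnotationSet | pd.DataFrame, plan: TilePlan,
                  dedup_radius: float = DEFAULT_DEDUP_RADIUS) -> AnnotationSet:
    """Translate per-tile points to the image frame and merge duplicates.

    Two points from the same worker and class, within ``dedup_radius`` of
    each other, lying in a region covered by more than one tile and coming
    from different tiles, are merged to their centroid (transitively, via
    connected components of such pairs).
    """
    if isinstance(annotations, AnnotationSet):
        if annotations.frame != "tile":
            raise ValueError("annotations must be in the tile frame")
        points, roster = annotations.points, annotations.roster
    else:
        points, roster = annotations, sorted(annotations["worker_id"].unique())

    translated = points.copy().reset_index(drop=True)
    known = {t[0] for t in plan.tiles}
    for i, p in translated.iterrows():
        tid = p["tile_id"]
        if tid not in known:
            raise KeyError(f"unknown tile {tid!r}")
        x0, y0, x1, y1 = plan.bounds(tid)
        if not (0 <= p["x"] <= x1 - x0 and 0 <= p["y"] <= y1 - y0):
            raise ValueError(
                f"point ({p['x']}, {p['y']}) outside its tile {tid!r}")
        translated.at[i, "x"] = p["x"] + x0
        translated.at[i, "y"] = p["y"] + y0

    kept_rows = []
    for (_worker, _cls), grp in translated.groupby(["worker_id", "class"],
                                                   sort=True):
        idx = grp.index.to_list()
        parent = {i: i for i in idx}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        xy = grp[["x", "y"]].to_numpy(float)
        tids = grp["tile_id"].to_list()
        in_overlap = [len(plan.tiles_containing(x, y)) >= 2 for x, y in xy]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if tids[a] == tids[b]:
                    continue
                if not (in_overlap[a] and in_overlap[b]):
                    continue
                if np.hypot(*(xy[a] - xy[b])) <= dedup_radius:
                    parent[find(idx[a])] = find(idx[b])
        groups: dict[int, list[int]] = {}
        for i in idx:
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            sub = translated.loc[members]
            row = dict(sub.iloc[0])
            row["x"] = float(sub["x"].mean())
            row["y"] = float(sub["y"].mean())
            row["tile_id"] = ""
            kept_rows.append(row)

    stitched = pd.DataFrame(kept_rows, columns=POINT_COLUMNS)
    stitched = stitched.sort_values(["worker_id", "class", "x", "y"],
                                    kind="stable").reset_index(drop=True)
    return AnnotationSet(points=stitched, roster=roster, frame="image")
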