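"""Simulated crowdworkers producing noisy point annotations.

Each worker is a :class:`WorkerProfile`: per-class sensitivity (chance of
clicking a true cell of the task class), a confusion table (chance of
labeling a confuser cell, e.g. a neuron, as the task class), a Poisson rate
of spurious clicks, Gaussian localization jitter, and the forced-point rule
of the annotation interface (at least one point per tile, otherwise one
random point is emitted).

Low-effort workers are modeled purely by low sensitivity; there is no
separate laziness process.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

POINT_COLUMNS = ["image_id", "tile_id", "worker_id", "class", "x", "y"]


def worker_seed(master_seed: int, worker_id: str) -> int:
    """Stable per-worker sub-seed, independent of iteration order.

    SHA-256 of ``"{master_seed}:{worker_id}"`` reduced below 2**31.
    """
    digest = hashlib.sha256(f"{master_seed}:{worker_id}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2 ** 31)


@dataclass
class WorkerProfile:
    worker_id: str
    sensitivity: dict[str, float] = field(default_factory=dict)
    confusion: dict[tuple[str, str], float] = field(default_factory=dict)
    fp_rate: float = 0.0
    localization_sd: float = 0.0
    forced_point: bool = True
    fp_class: str | None = None  # class of spurious clicks; default: the
    # class with the highest sensitivity

    def __post_init__(self) -> None:
        if self.fp_rate < 0 or self.localization_sd < 0:
            raise ValueError("fp_rate and localization_sd must be >= 0")
        outgoing: dict[str, float] = {}
        for c, p in self.sensitivity.items():
            if not 0 <= p <= 1:
                raise ValueError("sensitivities must lie in [0, 1]")
            outgoing[c] = outgoing.get(c, 0.0) + p
        for (true_c, _anno_c), p in self.confusion.items():
            if not 0 <= p <= 1:
                raise ValueError("confusion probabilities must lie in [0, 1]")
            outgoing[true_c] = outgoing.get(true_c, 0.0) + p
        for c, total in outgoing.items():
            if total > 1 + 1e-9:
                raise ValueError(
                    f"outgoing probabilities for true class {c!r} sum to "
                    f"{total:.3f} > 1")

    def default_fp_class(self) -> str:
        if self.fp_class is not None:
            return self.fp_class
        if self.sensitivity:
            return max(sorted(self.sensitivity), key=self.sensitivity.get)
        return "other"


@dataclass
class AnnotationSet:
    """Point annotations of a worker crowd plus the full worker roster.

    The roster includes workers who contributed no accepted point; ``frame``
    states whether coordinates are in the tile or the image frame.
    """

    points: pd.DataFrame
    roster: list[str]
    frame: str = "tile"

    def __post_init__(self) -> None:
        if self.frame not in ("tile", "image"):
            raise ValueError("frame must be 'tile' or 'image'")
        missing = [c for c in POINT_COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"points missing columns {missing}")

    def for_worker(self, worker_id: str) -> pd.DataFrame:
        return self.points[self.points["worker_id"] == worker_id]

    def to_csv(self, path, roster_path) -> None:
        self.points.to_csv(path, index=False)
        pd.DataFrame({"worker_id": self.roster}).to_csv(roster_path, index=False)

    @classmethod
    def from_csv(cls, path, roster_path, frame: str = "tile") -> "AnnotationSet":
        points = pd.read_csv(path, dtype={"image_id": str, "tile_id": str,
                                          "worker_id": str, "class": str})
        points["tile_id"] = points["tile_id"].fillna("")
        roster = pd.read_csv(roster_path, dtype=str)["worker_id"].tolist()
        return cls(points=points, roster=roster, frame=frame)


def _as_gt_frame(gt) -> pd.DataFrame:
    df = pd.DataFrame(gt)
    if "class" not in df.columns and "cell_class" in df.columns:
        df = df.rename(columns={"cell_class": "class"})
    for col in ("class", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"ground truth missing column {col!r}")
    return df


def simulate_worker(gt, bounds: tuple[float, float, float, float],
                    profile: WorkerProfile, seed: int,
                    image_id: str = "img", tile_id: str = "") -> pd.DataFrame:
    """Simulate one worker's clicks on a tile.

    ``gt`` holds the true cells visible in the tile (``class``, ``x``, ``y``
    in the tile frame); ``bounds`` is the half-open tile rectangle
    ``(x0, y0, x1, y1)``.  Each true cell of class ``c`` is annotated as
    class ``a`` with probability ``sensitivity[c]`` when ``a == c`` or
    ``confusion[(c, a)]`` otherwise, jittered by N(0, localization_sd^2) per
    axis.  Poisson(``fp_rate``) uniform spurious clicks are added.  If the
    forced-point rule applies and no point was produced, exactly one uniform
    random point is emitted.  Deterministic per seed.
    """
    x0, y0, x1, y1 = bounds
    if not (x1 > x0 and y1 > y0):
        raise ValueError("empty tile bounds")
    gt = _as_gt_frame(gt) if gt is not None and len(gt) else None
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def _emit(cls: str, x: float, y: float) -> None:
        rows.append({"image_id": image_id, "tile_id": tile_id,
                     "worker_id": profile.worker_id, "class": cls,
                     "x": float(np.clip(x, x0, np.nextafter(x1, x0))),
                     "y": float(np.clip(y, y0, np.nextafter(y1, y0)))})

    if gt is not None:
        for _, cell in gt.iterrows():
            true_c = cell["class"]
            bands: list[tuple[str, float]] = []
            p = profile.sensitivity.get(true_c, 0.0)
            if p > 0:
                bands.append((true_c, p))
            for (tc, ac), q in sorted(profile.confusion.items()):
                if tc == true_c and q > 0:
                    bands.append((ac, q))
            u = rng.random()
            acc = 0.0
            label = None
            for cls, q in bands:
                acc += q
                if u < acc:
                    label = cls
                    break
            if label is None:
                continue
            jx, jy = (rng.normal(0.0, profile.localization_sd, 2)
                      if profile.localization_sd > 0 else (0.0, 0.0))
            _emit(label, cell["x"] + jx, cell["y"] + jy)

    n_fp = int(rng.poisson(profile.fp_rate)) if profile.fp_rate > 0 else 0
    for _ in range(n_fp):
        _emit(profile.default_fp_class(),
              rng.uniform(x0, x1), rng.uniform(y0, y1))

    if profile.forced_point and not rows:
        _emit(profile.default_fp_class(),
              rng.uniform(x0, x1), rng.uniform(y0, y1))
    return pd.DataFrame(rows, columns=POINT_COLUMNS)


def default_profile(worker_id: str, target_class: str = "tumor",
                    sensitivity: float = 0.75, fp_rate: float = 1.0,
                    localization_sd: float = 3.0) -> WorkerProfile:
    """A plain reasonably attentive worker for one task class."""
    return WorkerProfile(worker_id=worker_id,
                         sensitivity={target_class: sensitivity},
                         fp_rate=fp_rate, localization_sd=localization_sd,
                         fp_class=target_class)


def sample_profiles(n: int, seed: int, target_class: str = "tumor",
                    sensitivity_range: tuple[float, float] = (0.5, 0.95),
                    fp_range: tuple[float, float] = (0.0, 3.0),
                    localization_sd: float = 3.0,
                    confusion: Mapping[tuple[str, str], tuple[float, float]]
                    | None = None) -> list[WorkerProfile]:
    """Draw a heterogeneous crowd: per-worker sensitivity and spurious-click
    rate uniform over the given ranges; optional per-pair confusion ranges."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        conf = {}
        if confusion:
            for pair, (lo, hi) in sorted(confusion.items()):
                conf[pair] = float(rng.uniform(lo, hi))
        profiles.append(WorkerProfile(
            worker_id=f"w{i:03d}",
            sensitivity={target_class: float(rng.uniform(*sensitivity_range))},
            confusion=conf,
            fp_rate=float(rng.uniform(*fp_range)),
            localization_sd=localization_sd,
            fp_class=target_class))
    return profiles


def simulate_crowd(gt, bounds, profiles: Sequence[WorkerProfile] | None = None,
                   n_workers: int | None = None, seed: int = 0,
                   image_id: str = "img", tile_id: str = "",
                   target_class: str = "tumor") -> AnnotationSet:
    """Simulate an independent crowd of workers on one tile.

    Either explicit ``profiles`` or ``n_workers`` (default crowd of identical
    :func:`default_profile` workers) must be given.  Each worker uses the
    sub-seed ``worker_seed(seed, worker_id)``, so the output is invariant to
    profile ordering.
    """
    if profiles is None:
        if n_workers is None:
            n_workers = 10
        if n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        profiles = [default_profile(f"w{i:03d}", target_class)
                    for i in range(n_workers)]
    if not profiles:
        raise ValueError("no worker profiles given")
    frames = []
    for profile in profiles:
        frames.append(simulate_worker(
            gt, bounds, profile, worker_seed(seed, profile.worker_id),
            image_id=image_id, tile_id=tile_id))
    frames = [f for f in frames if len(f)]
    points = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=POINT_COLUMNS))
    roster = sorted(p.worker_id for p in profiles)
    return AnnotationSet(points=points, roster=roster, frame="tile")
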