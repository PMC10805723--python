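"""Synthetic multiplexed immunofluorescence (mIF) tissue scenes.

Generates glioma-microenvironment-like regions containing tumor cells,
reactive astrocytes and confuser populations (neurons, endothelial cells,
immune cells), renders them to named marker channels and composes the
channel stack into RGB color variants for annotation or detector training.

The biology encoded here is the marker logic used to tell the two look-alike
classes apart: tumor cells of IDH1-mutant astrocytoma have lost nuclear ATRX
(DAPI-bright, ATRX-dark nuclei, GFAP-positive star-shaped cytoplasm), while
astrocytes retain ATRX (ATRX-bright nuclei, GFAP-positive star shape).
Neurons share the ATRX-positive nucleus but lack GFAP; endothelial cells are
elongated with faint GFAP in the vicinity.

Coordinates are 0-based, x rightward, y downward; sub-pixel cell centers are
allowed. Bounding boxes are half-open ``[x_min, x_max) x [y_min, y_max)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

#: All stainable channels: nuclear counterstain plus eight markers.
CHANNELS: tuple[str, ...] = (
    "DAPI", "ATRX", "GFAP", "IDH1", "MS4A4A", "CD68", "CD206", "CD3", "CD34",
)

#: Channels confined to the nucleus footprint; everything else is cytoplasmic.
NUCLEAR_CHANNELS = frozenset({"DAPI", "ATRX"})

CLASSES: tuple[str, ...] = (
    "tumor", "astrocyte", "neuron", "endothelial", "immune", "other",
)

# Class-typical marker expression in [0, 1].  Tumor cells are the only
# ATRX-negative class; neurons are the GFAP-negative ATRX-positive confuser.
DEFAULT_EXPRESSION: dict[str, dict[str, float]] = {
    "tumor": {"DAPI": 0.90, "ATRX": 0.0, "GFAP": 0.50, "IDH1": 0.60},
    "astrocyte": {"DAPI": 0.70, "ATRX": 0.80, "GFAP": 0.80},
    "neuron": {"DAPI": 0.70, "ATRX": 0.80},
    "endothelial": {"DAPI": 0.70, "ATRX": 0.70, "GFAP": 0.25, "CD34": 0.80},
    "immune": {"DAPI": 0.70, "ATRX": 0.60, "MS4A4A": 0.70, "CD68": 0.60,
               "CD206": 0.50, "CD3": 0.30},
    "other": {"DAPI": 0.70, "ATRX": 0.70},
}

# (nucleus_radius, cytoplasm_radius, arm_count) in pixels at 0.25 um/px.
# Nuclei ~8-11 um across; astrocyte/tumor processes reach ~25 um.
DEFAULT_GEOMETRY: dict[str, tuple[float, float, int]] = {
    "tumor": (16.0, 45.0, 5),
    "astrocyte": (16.0, 55.0, 6),
    "neuron": (22.0, 26.0, 0),
    "endothelial": (10.0, 40.0, 0),
    "immune": (10.0, 13.0, 0),
    "other": (12.0, 15.0, 0),
}

# Expected cells per pixel^2.  Derived from typical per-region counts
# (hundreds of tumor cells, a handful of astrocytes per 1860x1396 region).
DEFAULT_DENSITIES: dict[str, float] = {
    "tumor": 8.0e-5,
    "astrocyte": 8.0e-6,
    "neuron": 4.0e-6,
    "endothelial": 4.0e-6,
    "immune": 4.0e-6,
    "other": 8.0e-6,
}

#: Half-angle (radians) of a star arm wedge at the cell center.
ARM_HALF_ANGLE = 0.28


@dataclass
class CellSpec:
    """One cell: class, placement, shape parameters and marker expression."""

    cell_id: int
    cell_class: str
    center: tuple[float, float]
    nucleus_radius: float
    cytoplasm_radius: float
    arm_count: int = 0
    orientation: float = 0.0
    expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_class not in CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be > 0")
        if self.cytoplasm_radius < self.nucleus_radius:
            raise ValueError("cytoplasm_radius must be >= nucleus_radius")
        for ch in self.expression:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")


@dataclass
class Scene:
    """A synthetic tissue region with its ground-truth cell population."""

    width: int
    height: int
    cells: list[CellSpec]
    pixel_size: float = 0.25
    background_level: float = 0.05
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell ids must be unique")
        for c in self.cells:
            x, y = c.center
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"cell {c.cell_id} center outside scene")


@dataclass
class ChannelStack:
    """Ordered named intensity planes in [0, 1], all with equal shape."""

    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channel planes must share one shape")
        for name in self.channels:
            if name not in CHANNELS:
                raise ValueError(f"unknown channel {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]


@dataclass(frozen=True)
class VariantSpec:
    """An RGB rendering recipe: which channels appear, in what color/scale."""

    variant_id: str
    included_channels: tuple[str, ...]
    color_map: Mapping[str, tuple[tuple[float, float, float], float]]

    def __post_init__(self) -> None:
        for ch in self.included_channels:
            if ch not in self.color_map:
                raise ValueError(f"channel {ch!r} missing from color_map")
            _, scale = self.color_map[ch]
            if not 0 < scale <= 1:
                raise ValueError("intensity scale must lie in (0, 1]")


def variant_registry() -> dict[str, VariantSpec]:
    """The nine rendering variants.

    Var1 is the crowd-facing scheme (GFAP blue, ATRX red, DAPI white) and is
    fixed; Var2-Var4 vary colors/intensities of the same three channels,
    Var5-Var6 drop ATRX entirely (the IDH-wildtype situation), Var7-Var8 add
    extra markers without ATRX, and Var9 shows every channel.  Only Var1's
    colors are canonical; the rest are documented, configurable defaults.
    """
    white, red, blue = (1.0, 1.0, 1.0), (1.0, 0.0, 0.0), (0.0, 0.0, 1.0)
    green, magenta = (0.0, 1.0, 0.0), (1.0, 0.0, 1.0)
    cyan, yellow, orange = (0.0, 1.0, 1.0), (1.0, 1.0, 0.0), (1.0, 0.5, 0.0)
    v = {}
    v["Var1"] = VariantSpec("Var1", ("DAPI", "ATRX", "GFAP"),
                            {"DAPI": (white, 1.0), "ATRX": (red, 1.0),
                             "GFAP": (blue, 1.0)})
    v["Var2"] = VariantSpec("Var2", ("DAPI", "ATRX", "GFAP"),
                            {"DAPI": (white, 1.0), "ATRX": (red, 1.0),
                             "GFAP": (blue, 0.5)})
    v["Var3"] = VariantSpec("Var3", ("DAPI", "ATRX", "GFAP"),
                            {"DAPI": (white, 1.0), "ATRX": (magenta, 1.0),
                             "GFAP": (green, 1.0)})
    v["Var4"] = VariantSpec("Var4", ("DAPI", "ATRX", "GFAP"),
                            {"DAPI": (white, 0.6), "ATRX": (red, 0.7),
                             "GFAP": (blue, 1.0)})
    v["Var5"] = VariantSpec("Var5", ("DAPI", "GFAP"),
                            {"DAPI": (white, 1.0), "GFAP": (blue, 1.0)})
    v["Var6"] = VariantSpec("Var6", ("DAPI", "GFAP"),
                            {"DAPI": (white, 0.6), "GFAP": (cyan, 1.0)})
    v["Var7"] = VariantSpec("Var7", ("DAPI", "GFAP", "CD34", "CD68"),
                            {"DAPI": (white, 1.0), "GFAP": (blue, 1.0),
                             "CD34": (green, 1.0), "CD68": (orange, 1.0)})
    v["Var8"] = VariantSpec("Var8", ("DAPI", "GFAP", "MS4A4A", "CD206", "CD3"),
                            {"DAPI": (white, 1.0), "GFAP": (blue, 1.0),
                             "MS4A4A": (magenta, 1.0), "CD206": (green, 1.0),
                             "CD3": (yellow, 1.0)})
    v["Var9"] = VariantSpec("Var9", CHANNELS,
                            {"DAPI": (white, 1.0), "ATRX": (red, 1.0),
                             "GFAP": (blue, 1.0), "IDH1": ((0.5, 0.25, 0.0), 1.0),
                             "MS4A4A": (magenta, 1.0), "CD68": (orange, 1.0),
                             "CD206": (green, 1.0), "CD3": (yellow, 1.0),
                             "CD34": (cyan, 1.0)})
    return v


@dataclass
class SceneConfig:
    """Parameters of :func:`make_scene`.

    Densities are expected cells per pixel area; counts are Poisson draws.
    ``min_spacing`` is the minimum center-to-center distance enforced by
    rejection sampling.
    """

    width: int = 1860
    height: int = 1396
    pixel_size: float = 0.25
    densities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES))
    min_spacing: float = 40.0
    background_level: float = 0.05
    noise_sd: float = 0.02
    margin: float | None = None  # default: per-class nucleus radius
    expression_jitter: float = 0.05
    radius_jitter: float = 0.10


def make_scene(config: SceneConfig, seed: int) -> Scene:
    """Place cells at random with hard-core spacing and return a Scene.

    Per-class counts are Poisson with mean ``density * width * height``;
    centers are drawn uniformly and rejected when closer than ``min_spacing``
    to an already placed cell.  Deterministic for a fixed seed.
    """
    if config.width <= 0 or config.height <= 0:
        raise ValueError("scene dimensions must be positive")
    for cls, d in config.densities.items():
        if d < 0:
            raise ValueError(f"negative density for class {cls!r}")
        if cls not in CLASSES:
            raise ValueError(f"unknown cell class {cls!r}")
    rng = np.random.default_rng(seed)
    area = config.width * config.height
    counts = {cls: int(rng.poisson(d * area))
              for cls, d in sorted(config.densities.items())}

    cells: list[CellSpec] = []
    placed: list[tuple[float, float]] = []
    cell_id = 0
    for cls in sorted(counts):
        n = counts[cls]
        nr0, cr0, arms = DEFAULT_GEOMETRY[cls]
        margin = config.margin if config.margin is not None else nr0
        if 2 * margin >= min(config.width, config.height):
            margin = 0.0
        for _ in range(n):
            for attempt in range(200):
                x = rng.uniform(margin, config.width - margin)
                y = rng.uniform(margin, config.height - margin)
                if all((x - px) ** 2 + (y - py) ** 2 >= config.min_spacing ** 2
                       for px, py in placed):
                    break
            else:
                raise RuntimeError(
                    f"could not place a {cls!r} cell with spacing "
                    f"{config.min_spacing} after 200 attempts; lower the "
                    "density or the spacing")
            placed.append((x, y))
            jr = 1.0 + config.radius_jitter * rng.uniform(-1, 1)
            nr = max(2.0, nr0 * jr)
            cr = max(nr, cr0 * jr)
            expr = {}
            for ch, e in DEFAULT_EXPRESSION[cls].items():
                if e <= 0:
                    expr[ch] = 0.0
                else:
                    expr[ch] = float(np.clip(
                        e + config.expression_jitter * rng.uniform(-1, 1),
                        0.05, 1.0))
            cells.append(CellSpec(
                cell_id=cell_id, cell_class=cls, center=(x, y),
                nucleus_radius=nr, cytoplasm_radius=cr, arm_count=arms,
                orientation=float(rng.uniform(0, 2 * math.pi)),
                expression=expr))
            cell_id += 1
    return Scene(width=config.width, height=config.height, cells=cells,
                 pixel_size=config.pixel_size,
                 background_level=config.background_level,
                 noise_sd=config.noise_sd, seed=seed)


def _cell_footprints(cell: CellSpec, width: int, height: int):
    """Rasterize nucleus and cytoplasm masks of one cell.

    Returns ``(y0, x0, nucleus_mask, cytoplasm_mask)`` where the masks are
    boolean arrays for the window with origin ``(x0, y0)``.
    The cytoplasm of star-shaped classes is the union of the nucleus disc and
    ``arm_count`` circular-sector wedges of length ``cytoplasm_radius``;
    endothelial cells get an elongated ellipse along ``orientation``.
    """
    cx, cy = cell.center
    R = cell.cytoplasm_radius
    x0 = max(0, int(math.floor(cx - R - 1)))
    x1 = min(width, int(math.ceil(cx + R + 2)))
    y0 = max(0, int(math.floor(cy - R - 1)))
    y1 = min(height, int(math.ceil(cy + R + 2)))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    r = np.hypot(dx, dy)
    nucleus = r <= cell.nucleus_radius

    if cell.arm_count > 0:
        theta = np.arctan2(dy, dx) - cell.orientation
        step = 2 * math.pi / cell.arm_count
        ang = np.abs((theta + step / 2) % step - step / 2)
        cytoplasm = nucleus | ((r <= R) & (ang <= ARM_HALF_ANGLE))
    elif cell.cell_class == "endothelial":
        cos_o, sin_o = math.cos(cell.orientation), math.sin(cell.orientation)
        u = dx * cos_o + dy * sin_o
        v = -dx * sin_o + dy * cos_o
        minor = max(0.7 * cell.nucleus_radius, 0.2 * R)
        cytoplasm = nucleus | ((u / R) ** 2 + (v / minor) ** 2 <= 1.0)
    else:
        cytoplasm = r <= R
    return y0, x0, nucleus, cytoplasm


def render_channels(scene: Scene) -> ChannelStack:
    """Render a scene to per-marker intensity planes.

    Nuclear channels (DAPI, and ATRX iff expressed) paint the nucleus disc;
    cytoplasmic channels paint the full cell footprint.  Cell contributions
    add, a constant background level is added, Gaussian noise with
    ``scene.noise_sd`` is applied, and the result is clipped to [0, 1].
    Deterministic given ``scene.seed``.
    """
    h, w = scene.height, scene.width
    used = sorted({ch for c in scene.cells for ch in c.expression},
                  key=CHANNELS.index)
    names = [ch for ch in CHANNELS if ch in {"DAPI", "ATRX", "GFAP"} or ch in used]
    planes = {ch: np.zeros((h, w), dtype=np.float64) for ch in names}
    for cell in scene.cells:
        y0, x0, nucleus, cytoplasm = _cell_footprints(cell, w, h)
        for ch, e in cell.expression.items():
            if e <= 0:
                continue
            mask = nucleus if ch in NUCLEAR_CHANNELS else cytoplasm
            planes[ch][y0:y0 + mask.shape[0], x0:x0 + mask.shape[1]][mask] += e
    rng = np.random.default_rng(scene.seed)
    for ch in names:
        planes[ch] += scene.background_level
        if scene.noise_sd > 0:
            planes[ch] += rng.normal(0.0, scene.noise_sd, size=(h, w))
        np.clip(planes[ch], 0.0, 1.0, out=planes[ch])
    return ChannelStack(channels=planes)


def render_variant(stack: ChannelStack, variant: VariantSpec) -> np.ndarray:
    """Compose a channel stack into an RGB image per a variant recipe.

    ``rgb = clip(sum over included channels of plane * scale * color)``;
    channels outside the variant have no effect.
    """
    for ch in variant.included_channels:
        if ch not in stack.channels:
            raise KeyError(f"channel {ch!r} missing from stack")
    h, w = stack.shape
    rgb = np.zeros((h, w, 3), dtype=np.float64)
    for ch in variant.included_channels:
        color, scale = variant.color_map[ch]
        rgb += stack.channels[ch][:, :, None] * scale * np.asarray(color)
    return np.clip(rgb, 0.0, 1.0)


def ground_truth(scene: Scene) -> pd.DataFrame:
    """Export ground truth: cell centers and tight footprint bounding boxes.

    Boxes are half-open pixel bounds of the rasterized cell footprint,
    clipped to the scene.
    """
    rows = []
    for cell in scene.cells:
        y0, x0, _, cytoplasm = _cell_footprints(cell, scene.width, scene.height)
        ys, xs = np.nonzero(cytoplasm)
        rows.append({
            "cell_id": cell.cell_id,
            "class": cell.cell_class,
            "x": cell.center[0],
            "y": cell.center[1],
            "x_min": int(x0 + xs.min()),
            "y_min": int(y0 + ys.min()),
            "x_max": int(x0 + xs.max() + 1),
            "y_max": int(y0 + ys.max() + 1),
        })
    return pd.DataFrame(
        rows, columns=["cell_id", "class", "x", "y",
                       "x_min", "y_min", "x_max", "y_max"])


def write_channel_stack(path, stack: ChannelStack) -> None:
    """Write a stack as a multi-page float32 TIFF, channel name per page."""
    with tifffile.TiffWriter(path) as tif:
        for name, plane in stack.channels.items():
            tif.write(plane.astype(np.float32), description=name,
                      contiguous=False)


def read_channel_stack(path) -> ChannelStack:
    channels: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(path) as tif:
        for page in tif.pages:
            name = (page.description or "").strip()
            channels[name] = page.asarray().astype(np.float64)
    return ChannelStack(channels=channels)


def write_rgb_png(path, rgb: np.ndarray) -> None:
    """Write an RGB render in [0, 1] as an 8-bit PNG."""
    iio.imwrite(path, (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8))


def read_rgb_png(path) -> np.ndarray:
    arr = iio.imread(path)
    return arr[..., :3].astype(np.float64) / 255.0
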