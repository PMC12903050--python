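"""Synthetic bright-field chamber scenes, array mosaics and time-lapse assays.

Scenes emulate suspension cells trapped in microfluidic chambers imaged in
bright-field: a visible double-edged channel-wall contour, 1-15 round cells
(bright rim, darker annulus, mottled cytoplasm), defocus blur, and additive
noise calibrated so the per-image relative standard deviation (RSD) of pixel
intensities lands on a requested target.  Every generated pixel comes with
exact bounding-box ground truth, and everything is deterministic in the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .annot_io import BoundingBox, DetectionSet, write_voc

__all__ = [
    "CHAMBER_TYPES",
    "MAX_CELLS",
    "random_scenes",
    "SceneSpec",
    "AnnotatedImage",
    "AssayTruth",
    "PlacementError",
    "make_chamber_scene",
    "make_array_image",
    "make_timelapse_assay",
    "make_array_timelapse",
    "simulate_assay_detections",
    "write_dataset",
]

# Four chamber layouts differing in size (fraction of the canvas) and in the
# number of outlet channels cut into the bottom wall.
CHAMBER_TYPES: dict[str, dict] = {
    "small_single": {"frac": (0.60, 0.55), "outlets": 1},
    "medium_double": {"frac": (0.72, 0.70), "outlets": 2},
    "large_triple": {"frac": (0.86, 0.84), "outlets": 3},
    "wide_single": {"frac": (0.62, 0.90), "outlets": 1},
}

_BACKGROUND = 0.48
_MAX_PLACEMENT_ATTEMPTS = 5000


class PlacementError(RuntimeError):
    """Chamber too small/crowded to place the requested cells."""


# how many default-size cells fit comfortably per layout (rejection sampling
# starts failing beyond these)
MAX_CELLS = {
    "small_single": 5,
    "medium_double": 8,
    "large_triple": 14,
    "wide_single": 8,
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic chamber scene.

    ``image_size`` is (height, width); the default 100x200 matches the
    individual-chamber crop size used throughout.  ``cell_diameter_px`` is
    (mean, sd); at the nominal 0.65 um/px 10x scale a 15 um lymphoblast is
    ~23 px across.  ``target_rsd`` is the desired std/mean of pixel
    intensities of the final image.
    """

    image_size: tuple[int, int] = (100, 200)
    chamber_type: str = "medium_double"
    n_cells: int = 5
    cell_diameter_px: tuple[float, float] = (23.0, 2.0)
    wall_contrast: float = 0.18
    blur_sigma_px: float = 0.8
    target_rsd: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chamber_type not in CHAMBER_TYPES:
            raise ValueError(
                f"unknown chamber_type {self.chamber_type!r}; "
                f"choose from {sorted(CHAMBER_TYPES)}"
            )
        if not (1 <= self.n_cells <= 15):
            raise ValueError(f"n_cells must be in [1, 15], got {self.n_cells}")
        if not (0.10 <= self.target_rsd <= 0.35):
            raise ValueError(f"target_rsd must be in [0.10, 0.35], got {self.target_rsd}")
        if self.blur_sigma_px < 0:
            raise ValueError("blur_sigma_px must be >= 0")
        if self.cell_diameter_px[0] <= 2:
            raise ValueError("mean cell diameter must exceed 2 px")
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32")


@dataclass
class AnnotatedImage:
    """One image plus exact ground truth and generation metadata."""

    pixels: np.ndarray  # float in [0, 1], shape (H, W)
    boxes: list[BoundingBox]
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class AssayTruth:
    """Paired bright-field/fluorescence time-lapse with per-cell state truth.

    ``dead`` has shape (n_frames, n_cells); the dead state is absorbing.
    """

    frames: list[tuple[np.ndarray, np.ndarray]]
    boxes: list[BoundingBox]  # constant across frames (trapped cells)
    dead: np.ndarray
    mu_lo: float
    mu_hi: float
    sigma: float
    cell_values: np.ndarray  # per-frame, per-cell drawn fluorescence value
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_cells(self) -> int:
        return len(self.boxes)


# ---------------------------------------------------------------------------
# geometry helpers


def _chamber_rect(spec: SceneSpec) -> tuple[int, int, int, int]:
    """Chamber wall rectangle (y0, x0, y1, x1) on the canvas."""
    h, w = spec.image_size
    fh, fw = CHAMBER_TYPES[spec.chamber_type]["frac"]
    ch, cw = int(round(h * fh)), int(round(w * fw))
    y0 = (h - ch) // 2
    x0 = (w - cw) // 2
    return y0, x0, y0 + ch, x0 + cw


def _render_structure(spec: SceneSpec) -> np.ndarray:
    """Noise-free, blur-free chamber background: walls + outlet channels."""
    h, w = spec.image_size
    img = np.full((h, w), _BACKGROUND, dtype=np.float64)
    y0, x0, y1, x1 = _chamber_rect(spec)
    wc = spec.wall_contrast
    n_outlets = CHAMBER_TYPES[spec.chamber_type]["outlets"]

    # PDMS wall: bright line outside, dark line inside (refractive double edge)
    def _frame(a, b, c, d, value):
        img[a:b, c:d] = value

    # outer bright contour, 2 px
    _frame(y0 - 2, y0, x0 - 2, x1 + 2, _BACKGROUND + wc)
    _frame(y1, y1 + 2, x0 - 2, x1 + 2, _BACKGROUND + wc)
    _frame(y0 - 2, y1 + 2, x0 - 2, x0, _BACKGROUND + wc)
    _frame(y0 - 2, y1 + 2, x1, x1 + 2, _BACKGROUND + wc)
    # inner dark contour, 2 px
    _frame(y0, y0 + 2, x0, x1, _BACKGROUND - wc)
    _frame(y1 - 2, y1, x0, x1, _BACKGROUND - wc)
    _frame(y0, y1, x0, x0 + 2, _BACKGROUND - wc)
    _frame(y0, y1, x1 - 2, x1, _BACKGROUND - wc)

    # outlet channels: gaps in the bottom wall with short stub walls running
    # to the canvas edge
    gap = max(6, (x1 - x0) // 12)
    for k in range(n_outlets):
        cx = x0 + (k + 1) * (x1 - x0) // (n_outlets + 1)
        g0, g1 = cx - gap // 2, cx + gap // 2
        img[y1 - 2 : y1 + 2, g0:g1] = _BACKGROUND
        for wall_x in (g0 - 2, g1):
            img[y1 + 2 : h, wall_x : wall_x + 2] = _BACKGROUND + wc
            img[y1 + 2 : h, wall_x + 1 : wall_x + 2] = _BACKGROUND - wc * 0.5
    return img


def _place_cells(
    spec: SceneSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping cell centers inside the chamber.

    Minimum center distance is 0.9 x (r_i + r_j), permitting touching
    clusters.  Returns (centers[n, 2] as (cy, cx), radii[n]).
    """
    y0, x0, y1, x1 = _chamber_rect(spec)
    mean_d, sd_d = spec.cell_diameter_px
    radii = np.clip(
        rng.normal(mean_d / 2.0, sd_d / 2.0, size=spec.n_cells),
        mean_d / 4.0,
        mean_d,
    )
    radii = np.sort(radii)[::-1]  # place big cells first
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii:
        lo_y, hi_y = y0 + 3 + r, y1 - 3 - r
        lo_x, hi_x = x0 + 3 + r, x1 - 3 - r
        if hi_y <= lo_y or hi_x <= lo_x:
            raise PlacementError(
                f"chamber interior too small for a cell of radius {r:.1f} px"
            )
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            cy = rng.uniform(lo_y, hi_y)
            cx = rng.uniform(lo_x, hi_x)
            ok = all(
                np.hypot(cy - py, cx - px) >= 0.9 * (r + pr)
                for (py, px), pr in zip(centers, placed_r)
            )
            if ok:
                centers.append((cy, cx))
                placed_r.append(float(r))
                break
        else:
            raise PlacementError(
                f"could not place {spec.n_cells} cells of mean diameter "
                f"{mean_d:.0f} px in a {spec.chamber_type!r} chamber after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    return np.asarray(centers, dtype=np.float64), np.asarray(placed_r)


def _render_cell(
    img: np.ndarray, cy: float, cx: float, r: float, rng: np.random.Generator
) -> BoundingBox:
    """Draw one textured disk in place; returns the tight box of its pixels."""
    h, w = img.shape
    iy0 = max(0, int(np.floor(cy - r)) - 1)
    iy1 = min(h, int(np.ceil(cy + r)) + 2)
    ix0 = max(0, int(np.floor(cx - r)) - 1)
    ix1 = min(w, int(np.ceil(cx + r)) + 2)
    yy, xx = np.mgrid[iy0:iy1, ix0:ix1]
    d = np.hypot(yy + 0.0 - cy, xx + 0.0 - cx) / r
    inside = d <= 1.0

    patch = img[iy0:iy1, ix0:ix1]
    rim = inside & (d >= 0.72)
    annulus = inside & (d >= 0.40) & (d < 0.72)
    core = d < 0.40
    patch[rim] = _BACKGROUND + 0.30
    patch[annulus] = _BACKGROUND - 0.24
    patch[core] = _BACKGROUND + 0.06
    # mottled cytoplasm
    speckle = rng.normal(0.0, 0.05, size=patch.shape)
    patch[inside] += speckle[inside]

    ys, xs = np.nonzero(inside)
    return BoundingBox(
        x_min=float(ix0 + xs.min()),
        y_min=float(iy0 + ys.min()),
        x_max=float(ix0 + xs.max() + 1),
        y_max=float(iy0 + ys.max() + 1),
        label="cell",
    )


def _calibrate_rsd(
    img: np.ndarray, target_rsd: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Add clipped Gaussian noise so that std/mean of the result ~= target.

    The noise field is drawn once and rescaled, so the calibration loop does
    not consume extra random state and stays deterministic.
    """
    noise = rng.standard_normal(img.shape)
    mean = float(img.mean())
    base_var = float(img.var())
    target_std = target_rsd * mean
    if base_var > (0.9 * target_std) ** 2:
        # structure alone is already noisier than requested: compress contrast
        # toward the mean so the target stays reachable from below
        img = mean + (img - mean) * (0.9 * target_std / np.sqrt(base_var))
        base_var = float(img.var())
    extra = max(target_std**2 - base_var, 0.0)
    scale = float(np.sqrt(extra))
    out = np.clip(img + scale * noise, 0.0, 1.0)
    for _ in range(4):  # correct for clipping losses
        achieved = float(out.std() / out.mean())
        if abs(achieved - target_rsd) / target_rsd < 0.02 or scale == 0.0:
            break
        scale *= np.clip(target_rsd / achieved, 0.5, 2.0)
        out = np.clip(img + scale * noise, 0.0, 1.0)
    achieved = float(out.std() / out.mean())
    return out, achieved


# ---------------------------------------------------------------------------
# public operations


def make_chamber_scene(spec: SceneSpec) -> AnnotatedImage:
    """Render one chamber scene with exact bounding-box ground truth.

    Raises :class:`PlacementError` (never a partial scene) when the chamber
    cannot hold ``spec.n_cells`` non-overlapping cells.
    """
    rng = np.random.default_rng(spec.seed)
    img = _render_structure(spec)
    centers, radii = _place_cells(spec, rng)
    boxes = [
        _render_cell(img, cy, cx, r, rng) for (cy, cx), r in zip(centers, radii)
    ]
    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
    img, achieved = _calibrate_rsd(img, spec.target_rsd, rng)
    meta = {
        "spec": spec,
        "achieved_rsd": achieved,
        "centers": centers,
        "radii": radii,
    }
    return AnnotatedImage(pixels=img, boxes=boxes, meta=meta)


def random_scenes(
    n: int,
    seed: int,
    rsd_range: tuple[float, float] = (0.15, 0.27),
    blur_range: tuple[float, float] = (0.0, 1.5),
    chamber_types: Optional[Sequence[str]] = None,
    min_cells: int = 2,
) -> list[AnnotatedImage]:
    """Sample ``n`` feasible chamber scenes cycling through the layouts.

    Noise RSD and defocus blur are drawn uniformly from the given ranges
    (defaults match the imaging-condition spread emulated here: RSD
    0.15-0.27, blur up to 1.5 px); cell counts are uniform up to each
    layout's comfortable capacity.
    """
    rng = np.random.default_rng(seed)
    types = list(chamber_types or CHAMBER_TYPES)
    scenes = []
    for i in range(n):
        ct = types[i % len(types)]
        spec = SceneSpec(
            chamber_type=ct,
            n_cells=int(rng.integers(min_cells, MAX_CELLS.get(ct, 8) + 1)),
            target_rsd=float(rng.uniform(*rsd_range)),
            blur_sigma_px=float(rng.uniform(*blur_range)),
            seed=int(rng.integers(2**31)),
        )
        scenes.append(make_chamber_scene(spec))
    return scenes


def make_array_image(
    grid_rows: int,
    grid_cols: int,
    spec: SceneSpec,
    margin_px: int = 8,
    offset_px: tuple[int, int] = (0, 0),
    oversize_chambers: Sequence[int] = (),
    oversize_factor: float = 1.6,
) -> tuple[AnnotatedImage, list[BoundingBox]]:
    """Tile a grid of chamber scenes into one whole-array image.

    Each grid position gets its own seeded scene (seed derived from
    ``spec.seed`` and the position, so different seeds change cell layouts
    but never the chamber grid).  ``offset_px`` shifts the whole grid,
    allowing chambers to land partially off-canvas to exercise downstream
    edge filtering; their chamber boxes are clipped to the canvas and
    labelled ``"chamber_edge"``.  Indices in ``oversize_chambers`` (row-major)
    are rendered ``oversize_factor`` larger, to exercise oversize filtering.

    Returns the annotated array image (cell boxes in global coordinates)
    plus the chamber boxes.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    tile_h, tile_w = spec.image_size
    oy, ox = offset_px
    canvas_h = grid_rows * (tile_h + margin_px) + margin_px
    canvas_w = grid_cols * (tile_w + margin_px) + margin_px
    if canvas_h < tile_h or canvas_w < tile_w:
        raise ValueError("canvas smaller than one chamber tile")
    canvas = np.full((canvas_h, canvas_w), _BACKGROUND, dtype=np.float64)

    cell_boxes: list[BoundingBox] = []
    chamber_boxes: list[BoundingBox] = []
    rsds = []
    for row in range(grid_rows):
        for col in range(grid_cols):
            idx = row * grid_cols + col
            tile_spec = spec
            if idx in set(oversize_chambers):
                th, tw = spec.image_size
                tile_spec = replace(
                    spec,
                    image_size=(
                        int(round(th * oversize_factor)),
                        int(round(tw * oversize_factor)),
                    ),
                    cell_diameter_px=spec.cell_diameter_px,
                )
            tile_spec = replace(
                tile_spec, seed=int(np.random.default_rng((spec.seed, idx)).integers(2**31))
            )
            scene = make_chamber_scene(tile_spec)
            th, tw = scene.pixels.shape
            ty = margin_px + row * (tile_h + margin_px) + oy
            tx = margin_px + col * (tile_w + margin_px) + ox

            # paste with clipping
            sy0, sx0 = max(0, -ty), max(0, -tx)
            dy0, dx0 = max(0, ty), max(0, tx)
            sy1 = th - max(0, ty + th - canvas_h)
            sx1 = tw - max(0, tx + tw - canvas_w)
            if sy1 <= sy0 or sx1 <= sx0:
                continue  # entirely off-canvas
            canvas[dy0 : dy0 + (sy1 - sy0), dx0 : dx0 + (sx1 - sx0)] = scene.pixels[
                sy0:sy1, sx0:sx1
            ]

            y0, x0, y1, x1 = _chamber_rect(tile_spec)
            cb = BoundingBox(
                x_min=tx + x0 - 2, y_min=ty + y0 - 2, x_max=tx + x1 + 2, y_max=ty + y1 + 2,
                label="chamber",
            )
            clipped = cb.clipped(canvas_h, canvas_w)
            on_edge = (
                cb.x_min < 0 or cb.y_min < 0 or cb.x_max > canvas_w or cb.y_max > canvas_h
            )
            if on_edge:
                clipped = replace(clipped, label="chamber_edge")
            chamber_boxes.append(clipped)
            for b in scene.boxes:
                gb = b.translated(tx, ty)
                if gb.x_max <= 0 or gb.y_max <= 0 or gb.x_min >= canvas_w or gb.y_min >= canvas_h:
                    continue
                cell_boxes.append(gb.clipped(canvas_h, canvas_w))
            rsds.append(scene.meta["achieved_rsd"])

    meta = {
        "spec": spec,
        "grid": (grid_rows, grid_cols),
        "margin_px": margin_px,
        "offset_px": offset_px,
        "achieved_rsd": float(np.mean(rsds)) if rsds else float("nan"),
    }
    return AnnotatedImage(pixels=canvas, boxes=cell_boxes, meta=meta), chamber_boxes


def make_timelapse_assay(
    spec: SceneSpec,
    n_frames: int,
    kill_schedule: Sequence[float],
    seed: int,
    mu_lo: float = 0.15,
    mu_hi: float = 0.75,
    sigma: float = 0.05,
) -> AssayTruth:
    """Generate a paired bright-field/fluorescence time-lapse.

    Cells are trapped: positions (and hence ground-truth boxes) are constant
    across frames; bright-field frames differ only in the noise realization.
    ``kill_schedule`` gives the cumulative dead fraction per frame
    (non-decreasing — the dead state is absorbing); the number dead at frame
    ``t`` is ``floor(fraction * n_cells)``.  Per cell and frame, the mean
    fluorescence value is drawn from N(mu_lo, sigma) while live and
    N(mu_hi, sigma) once dead.
    """
    kill_schedule = list(kill_schedule)
    if len(kill_schedule) != n_frames:
        raise ValueError("kill_schedule length must equal n_frames")
    if any(f < 0 or f > 1 for f in kill_schedule):
        raise ValueError("kill_schedule values must be in [0, 1]")
    if any(b < a for a, b in zip(kill_schedule, kill_schedule[1:])):
        raise ValueError("kill_schedule must be non-decreasing (dead is absorbing)")
    if not mu_hi > mu_lo:
        raise ValueError("mu_hi must exceed mu_lo")

    rng = np.random.default_rng(seed)
    # structure + cells rendered once; noise re-drawn per frame
    struct_spec = spec
    struct_rng = np.random.default_rng(struct_spec.seed)
    img = _render_structure(struct_spec)
    centers, radii = _place_cells(struct_spec, struct_rng)
    boxes = [
        _render_cell(img, cy, cx, r, struct_rng)
        for (cy, cx), r in zip(centers, radii)
    ]
    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px)

    n_cells = len(boxes)
    n_dead = [int(np.floor(f * n_cells)) for f in kill_schedule]
    death_order = rng.permutation(n_cells)  # cells die in this fixed order
    dead = np.zeros((n_frames, n_cells), dtype=bool)
    for t, k in enumerate(n_dead):
        dead[t, death_order[:k]] = True

    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    frames: list[tuple[np.ndarray, np.ndarray]] = []
    cell_values = np.empty((n_frames, n_cells), dtype=np.float64)
    for t in range(n_frames):
        bf, _ = _calibrate_rsd(img, spec.target_rsd, rng)
        fl = np.zeros((h, w), dtype=np.float64)
        for i, ((cy, cx), r) in enumerate(zip(centers, radii)):
            mu = mu_hi if dead[t, i] else mu_lo
            val = float(rng.normal(mu, sigma))
            cell_values[t, i] = val
            fl[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = val
        fl = np.clip(fl + rng.normal(0.0, 0.01, size=fl.shape), 0.0, None)
        frames.append((bf, fl))

    return AssayTruth(
        frames=frames,
        boxes=boxes,
        dead=dead,
        mu_lo=mu_lo,
        mu_hi=mu_hi,
        sigma=sigma,
        cell_values=cell_values,
        meta={"spec": spec, "kill_schedule": kill_schedule, "seed": seed},
    )


def make_array_timelapse(
    grid_rows: int,
    grid_cols: int,
    spec: SceneSpec,
    n_frames: int,
    kill_schedule: Sequence[float],
    seed: int,
    margin_px: int = 6,
    **assay_kwargs,
) -> AssayTruth:
    """Tile independent per-chamber time-lapses into one whole-array assay.

    Each chamber follows the same cumulative ``kill_schedule`` (floor
    rounding applies per chamber); boxes and state arrays are pooled in
    global coordinates, which is how the array-level constant count N_total
    is defined downstream.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    tile_h, tile_w = spec.image_size
    canvas_h = grid_rows * (tile_h + margin_px) + margin_px
    canvas_w = grid_cols * (tile_w + margin_px) + margin_px
    frames = [
        (
            np.full((canvas_h, canvas_w), _BACKGROUND, dtype=np.float64),
            np.zeros((canvas_h, canvas_w), dtype=np.float64),
        )
        for _ in range(n_frames)
    ]
    boxes: list[BoundingBox] = []
    dead_cols, value_cols = [], []
    mu_lo = mu_hi = sigma = None
    for row in range(grid_rows):
        for col in range(grid_cols):
            idx = row * grid_cols + col
            rng = np.random.default_rng((seed, idx))
            tile_spec = replace(spec, seed=int(rng.integers(2**31)))
            sub = make_timelapse_assay(
                tile_spec,
                n_frames,
                kill_schedule,
                seed=int(rng.integers(2**31)),
                **assay_kwargs,
            )
            ty = margin_px + row * (tile_h + margin_px)
            tx = margin_px + col * (tile_w + margin_px)
            for t, (bf, fl) in enumerate(sub.frames):
                frames[t][0][ty : ty + tile_h, tx : tx + tile_w] = bf
                frames[t][1][ty : ty + tile_h, tx : tx + tile_w] = fl
            boxes.extend(b.translated(tx, ty) for b in sub.boxes)
            dead_cols.append(sub.dead)
            value_cols.append(sub.cell_values)
            mu_lo, mu_hi, sigma = sub.mu_lo, sub.mu_hi, sub.sigma
    return AssayTruth(
        frames=frames,
        boxes=boxes,
        dead=np.concatenate(dead_cols, axis=1),
        mu_lo=mu_lo,
        mu_hi=mu_hi,
        sigma=sigma,
        cell_values=np.concatenate(value_cols, axis=1),
        meta={
            "spec": spec,
            "grid": (grid_rows, grid_cols),
            "kill_schedule": list(kill_schedule),
            "seed": seed,
        },
    )


def simulate_assay_detections(
    truth: AssayTruth,
    seed: int,
    jitter_px: float = 1.0,
    conf_live: tuple[float, float] = (0.91, 0.99),
    conf_dying: tuple[float, float] = (0.55, 0.89),
) -> list[DetectionSet]:
    """Emulate per-frame detector output on an assay's bright-field frames.

    Boxes are the planted ground truth with small positional jitter.  Live
    cells get high confidence; cells that have turned apoptotic get a
    depressed confidence (morphology change), which is exactly the condition
    the constant-count selection rule downstream has to compensate for.
    """
    rng = np.random.default_rng(seed)
    h = truth.frames[0][0].shape[0]
    w = truth.frames[0][0].shape[1]
    out: list[DetectionSet] = []
    for t in range(truth.n_frames):
        det = DetectionSet(image_id=f"frame_{t:03d}", model_id="simulated")
        for i, box in enumerate(truth.boxes):
            dx, dy = rng.uniform(-jitter_px, jitter_px, size=2)
            lo, hi = conf_dying if truth.dead[t, i] else conf_live
            conf = float(rng.uniform(lo, hi))
            jittered = box.translated(float(dx), float(dy)).clipped(h, w)
            det.boxes.append(replace(jittered, confidence=conf))
        out.append(det)
    return out


def write_dataset(
    out_dir,
    images: Sequence[AnnotatedImage],
    prefix: str = "scene",
    image_format: str = "png",
) -> Path:
    """Write images (8-bit PNG or 16-bit TIFF), VOC XML and a manifest CSV."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "n_cells", "seed", "chamber_type"])
        for i, ann in enumerate(images):
            name = f"{prefix}_{i:04d}.{image_format}"
            if image_format == "tif":
                iio.imwrite(out_dir / name, (ann.pixels * 65535).astype(np.uint16))
            else:
                iio.imwrite(out_dir / name, (ann.pixels * 255).astype(np.uint8))
            write_voc(
                out_dir / f"{prefix}_{i:04d}.xml", name, ann.boxes, ann.pixels.shape
            )
            spec: Optional[SceneSpec] = ann.meta.get("spec")
            writer.writerow(
                [
                    name,
                    len(ann.boxes),
                    spec.seed if spec else "",
                    spec.chamber_type if spec else "",
                ]
            )
    return manifest
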