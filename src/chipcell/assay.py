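"""Time-lapse cell-killing-assay quantification.

The trap-array design keeps the total cell count constant over time, which
licenses the constant-count detection rule: count cells at t0 with the
working confidence cutoff (0.9), then at later timepoints keep exactly the
N_total highest-confidence detections — equivalent to lowering the cutoff
until the count matches.  Per-cell fluorescence is the mean of the reporter
channel inside each detection box; the live/dead intensity threshold is the
local minimum between the two modes of the end-point fluorescence histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annot_io import BoundingBox, DetectionSet

__all__ = [
    "CellTrajectory",
    "AssayResult",
    "BimodalityError",
    "count_t0",
    "select_constant_count",
    "roi_mean_fluorescence",
    "bimodal_threshold",
    "build_trajectories",
    "survival_curve",
    "quantify_assay",
]

log = logging.getLogger(__name__)


class BimodalityError(ValueError):
    """Histogram has no interior minimum between two distinct peaks."""


@dataclass
class CellTrajectory:
    cell_id: int
    timepoints: list[int] = field(default_factory=list)
    boxes: list[BoundingBox] = field(default_factory=list)
    fluorescence: list[float] = field(default_factory=list)
    dead: list[bool] = field(default_factory=list)
    complete: bool = True  # False when the track terminated early

    @property
    def roi_sizes(self) -> list[float]:
        # recorded as metadata only; never feeds the live/dead call
        return [b.area for b in self.boxes]


@dataclass
class AssayResult:
    n_total: int
    timepoints: list[int]
    live_fraction: list[float]
    effective_thresholds: list[float]
    intensity_threshold: float
    shortfall: list[int] = field(default_factory=list)  # missing dets per t


def count_t0(dets_t0: DetectionSet, conf: float = 0.9) -> int:
    """N_total: detections at t0 with confidence >= the working cutoff."""
    return sum(
        1 for b in dets_t0.boxes if b.confidence is not None and b.confidence >= conf
    )


def select_constant_count(
    dets_t: DetectionSet, n_total: int
) -> tuple[DetectionSet, float]:
    """Keep the ``n_total`` highest-confidence detections.

    Equivalent to lowering the confidence cutoff until the detected count
    matches the t0 total (exact top-N keeps it deterministic under ties:
    x_min then y_min).  Returns the selection and the effective threshold —
    the confidence of the last kept box.  A shortfall (fewer raw detections
    than ``n_total``) returns everything and logs a warning.
    """
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    ranked = dets_t.sorted_boxes()
    if n_total == 0:
        return DetectionSet(image_id=dets_t.image_id, model_id=dets_t.model_id), 1.0
    if len(ranked) < n_total:
        log.warning(
            "constant-count shortfall on %s: %d detections for N_total=%d",
            dets_t.image_id,
            len(ranked),
            n_total,
        )
    kept = ranked[:n_total]
    eff = kept[-1].confidence if kept else 1.0
    out = DetectionSet(
        image_id=dets_t.image_id,
        boxes=kept,
        model_id=dets_t.model_id,
        threshold=eff,
    )
    return out, float(eff if eff is not None else 0.0)


def roi_mean_fluorescence(box: BoundingBox, fluor_image) -> float:
    """Mean fluorescence inside the half-open box (integer pixel footprint)."""
    img = np.asarray(fluor_image, dtype=np.float64)
    h, w = img.shape
    if box.x_min < 0 or box.y_min < 0 or box.x_max > w or box.y_max > h:
        raise ValueError(
            f"box ({box.x_min}, {box.y_min}, {box.x_max}, {box.y_max}) outside "
            f"{h}x{w} image"
        )
    y0, y1 = int(np.floor(box.y_min)), int(np.ceil(box.y_max))
    x0, x1 = int(np.floor(box.x_min)), int(np.ceil(box.x_max))
    roi = img[y0:y1, x0:x1]
    return float(roi.mean())


def bimodal_threshold(values: Sequence[float], n_bins: int = 50) -> float:
    """Live/dead cutoff: the local histogram minimum between the two modes.

    Builds an ``n_bins`` histogram over [min, max], smooths it with a 3-bin
    moving average, finds the two highest local maxima, and returns the
    center of the lowest bin strictly between them.  Raises
    :class:`BimodalityError` when the histogram is unimodal, in which case a
    manual threshold must be supplied.
    """
    values = np.asarray(list(values), dtype=np.float64)
    if values.size < 10:
        raise ValueError(f"need >= 10 values, got {values.size}")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise BimodalityError("all values identical: histogram is unimodal")
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(counts.astype(np.float64), kernel, mode="same")

    # local maxima (plateau-tolerant: strictly above one side, >= other)
    padded = np.concatenate([[-1.0], smooth, [-1.0]])
    is_peak = (padded[1:-1] > padded[:-2]) & (padded[1:-1] >= padded[2:])
    peaks = np.flatnonzero(is_peak)
    if len(peaks) < 2:
        raise BimodalityError(
            "histogram is unimodal; supply a manual intensity threshold"
        )
    top2 = peaks[np.argsort(smooth[peaks], kind="stable")[::-1][:2]]
    p_lo, p_hi = int(top2.min()), int(top2.max())
    if p_hi - p_lo < 2:
        raise BimodalityError(
            "no interior bin between the two main peaks; supply a manual threshold"
        )
    interior = smooth[p_lo + 1 : p_hi]
    # a real valley must dip well below the smaller mode, otherwise the two
    # "peaks" are just noise bumps on a unimodal histogram
    if interior.min() > 0.6 * min(smooth[p_lo], smooth[p_hi]):
        raise BimodalityError(
            "histogram is effectively unimodal (no clear valley between the "
            "two highest peaks); supply a manual threshold"
        )
    # ties (e.g. an empty plateau between well-separated modes) resolve to the
    # central minimal bin, which converges on the mixture crossing point
    minimal = np.flatnonzero(interior == interior.min())
    k = p_lo + 1 + int(minimal[len(minimal) // 2])
    return float(0.5 * (edges[k] + edges[k + 1]))


def build_trajectories(
    per_timepoint_boxes: Sequence[DetectionSet], max_disp_px: float
) -> list[CellTrajectory]:
    """Link detections across timepoints by greedy nearest-center matching.

    Trapped cells barely move, so matching is purely positional: between
    consecutive timepoints, pairs are linked in order of increasing center
    distance while that distance is <= ``max_disp_px``.  Unmatched boxes
    start new trajectories; trajectories that miss a timepoint terminate and
    are flagged incomplete.
    """
    trajectories: list[CellTrajectory] = []
    active: dict[int, CellTrajectory] = {}  # index into previous frame boxes
    prev_boxes: list[BoundingBox] = []
    next_id = 0
    n_frames = len(per_timepoint_boxes)
    for t, dets in enumerate(per_timepoint_boxes):
        boxes = dets.sorted_boxes()
        if t == 0:
            for b in boxes:
                traj = CellTrajectory(cell_id=next_id)
                next_id += 1
                traj.timepoints.append(t)
                traj.boxes.append(b)
                trajectories.append(traj)
            active = {i: trajectories[i] for i in range(len(boxes))}
            prev_boxes = boxes
            continue
        # distance matrix previous x current
        pairs = []
        for i, pb in enumerate(prev_boxes):
            if i not in active:
                continue
            for j, cb in enumerate(boxes):
                d = float(np.hypot(pb.center[0] - cb.center[0], pb.center[1] - cb.center[1]))
                if d <= max_disp_px:
                    pairs.append((d, i, j))
        pairs.sort(key=lambda x: (x[0], x[1], x[2]))
        used_prev: set[int] = set()
        used_cur: set[int] = set()
        new_active: dict[int, CellTrajectory] = {}
        for d, i, j in pairs:
            if i in used_prev or j in used_cur:
                continue
            used_prev.add(i)
            used_cur.add(j)
            traj = active[i]
            traj.timepoints.append(t)
            traj.boxes.append(boxes[j])
            new_active[j] = traj
        for i, traj in active.items():
            if i not in used_prev:
                traj.complete = False  # track lost before the last frame
        for j, cb in enumerate(boxes):
            if j not in used_cur:
                traj = CellTrajectory(cell_id=next_id, complete=(t == 0))
                next_id += 1
                traj.timepoints.append(t)
                traj.boxes.append(cb)
                trajectories.append(traj)
                new_active[j] = traj
        active = new_active
        prev_boxes = boxes
    for traj in trajectories:
        if traj.timepoints and traj.timepoints[-1] != n_frames - 1:
            traj.complete = False
        if traj.timepoints and traj.timepoints[0] != 0:
            traj.complete = False
    return trajectories


def survival_curve(
    trajectories: Sequence[CellTrajectory],
    threshold: float,
    n_total: Optional[int] = None,
    absorbing: bool = True,
) -> AssayResult:
    """Live fraction per timepoint from per-cell fluorescence trajectories.

    A cell is dead at ``t`` iff its mean fluorescence is >= ``threshold``
    (the apoptosis reporter brightens in dying cells).  With ``absorbing``
    (default, matching the trapped-cell assumption) a cell stays dead once
    called dead.
    """
    timepoints = sorted({t for traj in trajectories for t in traj.timepoints})
    if n_total is None:
        n_total = len(trajectories)
    live_fraction = []
    for traj in trajectories:
        dead = False
        traj.dead = []
        for f in traj.fluorescence:
            call = f >= threshold
            if absorbing:
                dead = dead or call
                traj.dead.append(dead)
            else:
                traj.dead.append(call)
    for t in timepoints:
        n_dead = 0
        for traj in trajectories:
            if t in traj.timepoints:
                k = traj.timepoints.index(t)
                if k < len(traj.dead) and traj.dead[k]:
                    n_dead += 1
        live_fraction.append((n_total - n_dead) / n_total if n_total else 1.0)
    return AssayResult(
        n_total=n_total,
        timepoints=timepoints,
        live_fraction=live_fraction,
        effective_thresholds=[],
        intensity_threshold=threshold,
    )


def quantify_assay(
    fluor_frames: Sequence[np.ndarray],
    dets_per_frame: Sequence[DetectionSet],
    conf_t0: float = 0.9,
    max_disp_px: float = 5.0,
    n_bins: int = 50,
    absorbing: bool = True,
    manual_threshold: Optional[float] = None,
) -> tuple[AssayResult, list[CellTrajectory]]:
    """Full quantification pipeline for one time-lapse.

    Steps: N_total at t0 at the working cutoff -> constant-count selection
    per later frame -> trajectories -> per-timepoint ROI mean fluorescence ->
    bimodal threshold on the final frame's values -> survival curve.
    """
    if len(fluor_frames) != len(dets_per_frame):
        raise ValueError("one DetectionSet per fluorescence frame required")
    n_total = count_t0(dets_per_frame[0], conf=conf_t0)
    selected: list[DetectionSet] = []
    thresholds: list[float] = []
    shortfall: list[int] = []
    for t, dets in enumerate(dets_per_frame):
        if t == 0:
            from .detector import filter_by_confidence

            sel = filter_by_confidence(dets, conf_t0)
            eff = conf_t0
        else:
            sel, eff = select_constant_count(dets, n_total)
        selected.append(sel)
        thresholds.append(float(eff))
        shortfall.append(max(0, n_total - len(sel.boxes)))

    trajectories = build_trajectories(selected, max_disp_px=max_disp_px)
    for traj in trajectories:
        traj.fluorescence = [
            roi_mean_fluorescence(b, fluor_frames[t])
            for t, b in zip(traj.timepoints, traj.boxes)
        ]

    last_t = len(fluor_frames) - 1
    final_values = [
        traj.fluorescence[traj.timepoints.index(last_t)]
        for traj in trajectories
        if last_t in traj.timepoints
    ]
    if manual_threshold is not None:
        thr = manual_threshold
    else:
        thr = bimodal_threshold(final_values, n_bins=n_bins)

    result = survival_curve(trajectories, thr, n_total=n_total, absorbing=absorbing)
    result.effective_thresholds = thresholds
    result.shortfall = shortfall
    return result, trajectories
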