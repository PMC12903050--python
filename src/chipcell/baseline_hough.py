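"""Circular-Hough-transform baseline detector with a radius band filter.

Textbook pipeline: Sobel gradient magnitude, Otsu-thresholded into an edge
map, 3-D (cx, cy, r) Hough accumulator, peak picking with non-maximum
suppression, then a radius band filter (default 5-100 px).  Each accepted
circle (cx, cy, r) is emitted as the bounding box (cx-r, cy-r, cx+r, cy+r)
with the normalized accumulator peak value as its confidence, so its output
is directly comparable with the learned detector's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import hough_circle, hough_circle_peaks

from .annot_io import BoundingBox, DetectionSet

__all__ = ["HoughConfig", "detect_circles"]


@dataclass(frozen=True)
class HoughConfig:
    """Circle-search parameters.

    ``suppression_factor`` scales the duplicate-suppression radius: peaks
    whose centers lie within ``suppression_factor * r`` of a stronger peak
    are dropped.  Set it to 0 to reproduce the multiple-circles-per-cell
    failure mode instead of hiding it.
    """

    radius_min_px: int = 5
    radius_max_px: int = 100
    radius_step: int = 1
    edge_sigma: float = 1.0
    peak_threshold: float = 0.6  # min fraction of the circle rim that must vote
    suppression_factor: float = 0.5
    max_detections: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.radius_min_px < self.radius_max_px):
            raise ValueError(
                f"need 0 < radius_min_px < radius_max_px, got "
                f"{self.radius_min_px}, {self.radius_max_px}"
            )
        if self.radius_step < 1:
            raise ValueError("radius_step must be >= 1")
        if self.max_detections < 1:
            raise ValueError("max_detections must be >= 1")


def _edge_map(image: np.ndarray, sigma: float) -> np.ndarray:
    smooth = ndimage.gaussian_filter(image.astype(np.float64), sigma)
    grad = np.hypot(ndimage.sobel(smooth, axis=0), ndimage.sobel(smooth, axis=1))
    if grad.max() <= 0:
        return np.zeros_like(grad, dtype=bool)
    thresh = threshold_otsu(grad)
    return grad > thresh


def detect_circles(image, config: HoughConfig = HoughConfig()) -> DetectionSet:
    """Detect circles in a single-channel image.

    Circles with radius outside ``[radius_min_px, radius_max_px]`` are never
    emitted, and no returned box has a side outside ``[2*radius_min,
    2*radius_max]``.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {image.shape}")
    edges = _edge_map(image, config.edge_sigma)
    det = DetectionSet(image_id="", model_id="hough")
    if not edges.any():
        return det

    radii = np.arange(
        config.radius_min_px, config.radius_max_px + 1, config.radius_step
    )
    # hough_circle normalizes each radius plane by the rim length, so peak
    # values are the fraction of the circle's rim supported by edge pixels
    accum = hough_circle(edges, radii)
    if float(accum.max()) <= 0:
        return det
    min_dist = max(1, int(round(config.suppression_factor * config.radius_min_px)))
    accums, cxs, cys, rs = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=min_dist,
        min_ydistance=min_dist,
        threshold=config.peak_threshold,
        total_num_peaks=4 * config.max_detections,
        normalize=False,
    )

    kept: list[tuple[float, float, float, float]] = []
    for a, cx, cy, r in zip(accums, cxs, cys, rs):
        # duplicate suppression scaled by the *candidate's* radius
        if any(
            np.hypot(cx - kx, cy - ky) < config.suppression_factor * max(r, kr)
            for _, kx, ky, kr in kept
        ):
            continue
        kept.append((float(a), float(cx), float(cy), float(r)))
        if len(kept) >= config.max_detections:
            break

    for a, cx, cy, r in kept:
        # box kept unclipped so side length always stays in the radius band
        det.boxes.append(
            BoundingBox(
                x_min=cx - r,
                y_min=cy - r,
                x_max=cx + r,
                y_max=cy + r,
                label="cell",
                confidence=min(1.0, a),  # rim-completeness fraction
            )
        )
    det.boxes = det.sorted_boxes()
    return det
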