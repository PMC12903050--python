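"""Crop whole-array images into per-chamber images from chamber detections.

Chamber detections come from a detector trained on the chamber class (see
:mod:`chipcell.detector`); this module is pure geometry: it filters out
oversized inferences and inferences touching the image edges (chambers
partially out of the field of view), then returns padded crops together with
their global offsets so downstream cell boxes can be mapped back into array
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .annot_io import BoundingBox, DetectionSet

__all__ = ["ChamberCrop", "split_array", "map_to_array_coords", "map_to_crop_coords"]


@dataclass
class ChamberCrop:
    """One chamber crop plus the (dy, dx) offset of its origin in the array."""

    pixels: np.ndarray
    offset: tuple[int, int]  # (y, x) of crop origin in array coordinates
    source_box: BoundingBox


def split_array(
    image,
    chamber_dets: DetectionSet,
    oversize_factor: float = 1.5,
    edge_margin_px: int = 2,
    pad_px: int = 4,
) -> list[ChamberCrop]:
    """Crop one chamber image per surviving chamber detection.

    Detections whose area exceeds ``oversize_factor`` times the median
    detected area are dropped, as are detections with any side within
    ``edge_margin_px`` of an image border.  Crops are padded by ``pad_px``
    (clipped to bounds).  Zero detections yield an empty list with a
    warning, never an error.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if not chamber_dets.boxes:
        warnings.warn("no chamber detections; returning no crops", stacklevel=2)
        return []
    areas = np.array([b.area for b in chamber_dets.boxes])
    median_area = float(np.median(areas))

    crops: list[ChamberCrop] = []
    for box in chamber_dets.sorted_boxes():
        if box.area > oversize_factor * median_area:
            continue
        if (
            box.x_min < edge_margin_px
            or box.y_min < edge_margin_px
            or box.x_max > w - edge_margin_px
            or box.y_max > h - edge_margin_px
        ):
            continue
        y0 = max(0, int(np.floor(box.y_min)) - pad_px)
        x0 = max(0, int(np.floor(box.x_min)) - pad_px)
        y1 = min(h, int(np.ceil(box.y_max)) + pad_px)
        x1 = min(w, int(np.ceil(box.x_max)) + pad_px)
        crops.append(
            ChamberCrop(pixels=image[y0:y1, x0:x1], offset=(y0, x0), source_box=box)
        )
    return crops


def map_to_array_coords(box: BoundingBox, offset: tuple[int, int]) -> BoundingBox:
    """Translate a crop-local box into whole-array coordinates."""
    dy, dx = offset
    return box.translated(dx, dy)


def map_to_crop_coords(box: BoundingBox, offset: tuple[int, int]) -> BoundingBox:
    """Inverse of :func:`map_to_array_coords`."""
    dy, dx = offset
    return box.translated(-dx, -dy)
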