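"""Bounding-box annotation I/O: Pascal VOC XML, inference CSV, COCO JSON (read-only).

Internal coordinate convention is 0-based, half-open ``[x_min, x_max) x
[y_min, y_max)`` everywhere; only the VOC layer converts to/from VOC's
1-based inclusive pixels, so box area is always
``(x_max - x_min) * (y_max - y_min)`` with no off-by-one ambiguity.
"""

from __future__ import annotations

import csv
import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "BoundingBox",
    "DetectionSet",
    "AnnotationError",
    "read_voc",
    "write_voc",
    "write_inferences_csv",
    "read_inferences_csv",
    "read_coco",
]

CSV_COLUMNS = ("image_id", "x_min", "y_min", "x_max", "y_max", "label", "confidence")


class AnnotationError(ValueError):
    """Raised for malformed annotation files or invalid box geometry."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in 0-based half-open pixel coordinates.

    ``confidence`` is ``None`` for ground-truth boxes and a probability in
    [0, 1] for detector output.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str = "cell"
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise AnnotationError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise AnnotationError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def translated(self, dx: float, dy: float) -> "BoundingBox":
        return replace(
            self,
            x_min=self.x_min + dx,
            y_min=self.y_min + dy,
            x_max=self.x_max + dx,
            y_max=self.y_max + dy,
        )

    def clipped(self, height: int, width: int) -> "BoundingBox":
        """Clip to image bounds; raises if nothing remains."""
        return replace(
            self,
            x_min=max(0.0, self.x_min),
            y_min=max(0.0, self.y_min),
            x_max=min(float(width), self.x_max),
            y_max=min(float(height), self.y_max),
        )


def _sort_key(box: BoundingBox) -> tuple:
    conf = box.confidence if box.confidence is not None else 1.0
    return (-conf, box.x_min, box.y_min)


@dataclass
class DetectionSet:
    """Detections for one image, sorted by descending confidence on write."""

    image_id: str
    boxes: list[BoundingBox] = field(default_factory=list)
    model_id: str = ""
    threshold: Optional[float] = None

    def sorted_boxes(self) -> list[BoundingBox]:
        """Boxes by descending confidence, ties broken by x_min then y_min."""
        return sorted(self.boxes, key=_sort_key)

    def __len__(self) -> int:
        return len(self.boxes)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def read_voc(xml_path, return_size: bool = False):
    """Parse one Pascal VOC XML annotation file.

    VOC's 1-based inclusive pixel coordinates are converted to the internal
    0-based half-open convention (``x_min = xmin - 1``, ``x_max = xmax``).

    Returns ``(image_ref, boxes)``, or ``(image_ref, boxes, (height, width))``
    when ``return_size`` is true.
    """
    xml_path = Path(xml_path)
    try:
        root = ET.parse(xml_path).getroot()
    except ET.ParseError as exc:
        raise AnnotationError(f"{xml_path}: malformed XML ({exc})") from exc

    fname = root.findtext("filename")
    if fname is None:
        raise AnnotationError(f"{xml_path}: missing <filename> element")
    size_el = root.find("size")
    if size_el is None:
        raise AnnotationError(f"{xml_path}: missing <size> element")
    try:
        width = int(size_el.findtext("width"))
        height = int(size_el.findtext("height"))
    except (TypeError, ValueError) as exc:
        raise AnnotationError(f"{xml_path}: bad <size> contents") from exc

    boxes: list[BoundingBox] = []
    for i, obj in enumerate(root.iter("object")):
        label = obj.findtext("name") or "cell"
        bb = obj.find("bndbox")
        if bb is None:
            raise AnnotationError(f"{xml_path}: object {i} missing <bndbox>")
        try:
            xmin = float(bb.findtext("xmin"))
            ymin = float(bb.findtext("ymin"))
            xmax = float(bb.findtext("xmax"))
            ymax = float(bb.findtext("ymax"))
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"{xml_path}: object {i} has bad <bndbox>") from exc
        if xmax <= xmin or ymax <= ymin:
            raise AnnotationError(
                f"{xml_path}: object {i} degenerate bndbox "
                f"(xmin={xmin}, ymin={ymin}, xmax={xmax}, ymax={ymax})"
            )
        if xmin < 1 or ymin < 1 or xmax > width or ymax > height:
            raise AnnotationError(
                f"{xml_path}: object {i} bndbox outside declared image size "
                f"{width}x{height}"
            )
        boxes.append(
            BoundingBox(xmin - 1.0, ymin - 1.0, float(xmax), float(ymax), label=label)
        )
    if return_size:
        return fname, boxes, (height, width)
    return fname, boxes


def write_voc(xml_path, image_ref: str, boxes: Sequence[BoundingBox], image_size) -> Path:
    """Write a Pascal VOC XML file (inverse of :func:`read_voc`).

    Non-integer internal coordinates are rounded half-up.  Element order is
    deterministic; boxes are written in the order given.
    """
    height, width = int(image_size[0]), int(image_size[1])
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "."
    ET.SubElement(root, "filename").text = str(image_ref)
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(width)
    ET.SubElement(size, "height").text = str(height)
    ET.SubElement(size, "depth").text = "1"
    for box in boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = box.label
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = str(_round_half_up(box.x_min) + 1)
        ET.SubElement(bb, "ymin").text = str(_round_half_up(box.y_min) + 1)
        ET.SubElement(bb, "xmax").text = str(_round_half_up(box.x_max))
        ET.SubElement(bb, "ymax").text = str(_round_half_up(box.y_max))
    ET.indent(root)
    xml_path = Path(xml_path)
    ET.ElementTree(root).write(xml_path, encoding="unicode")
    return xml_path


def write_inferences_csv(detections: Sequence[DetectionSet], path) -> Path:
    """Write detections as a flat CSV (one row per box, header always present).

    Columns are exactly ``image_id, x_min, y_min, x_max, y_max, label,
    confidence``; within each image boxes are ordered by descending
    confidence.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for det in detections:
            for box in det.sorted_boxes():
                conf = "" if box.confidence is None else repr(float(box.confidence))
                writer.writerow(
                    [
                        det.image_id,
                        repr(float(box.x_min)),
                        repr(float(box.y_min)),
                        repr(float(box.x_max)),
                        repr(float(box.y_max)),
                        box.label,
                        conf,
                    ]
                )
    return path


def read_inferences_csv(path) -> list[DetectionSet]:
    """Read a CSV written by :func:`write_inferences_csv`, grouped by image."""
    path = Path(path)
    sets: dict[str, DetectionSet] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != CSV_COLUMNS:
            raise AnnotationError(f"{path}: unexpected CSV header {header}")
        for row in reader:
            image_id, x0, y0, x1, y1, label, conf = row
            det = sets.setdefault(image_id, DetectionSet(image_id=image_id))
            det.boxes.append(
                BoundingBox(
                    float(x0),
                    float(y0),
                    float(x1),
                    float(y1),
                    label=label,
                    confidence=None if conf == "" else float(conf),
                )
            )
    return list(sets.values())


def read_coco(json_path) -> dict[str, list[BoundingBox]]:
    """Read COCO-style detection/annotation JSON (secondary, read-only).

    COCO ``bbox`` is ``[x, y, width, height]``; converted to the internal
    half-open corners.  Returns a mapping from image file name to boxes.
    """
    json_path = Path(json_path)
    with open(json_path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        images = {img["id"]: img["file_name"] for img in doc["images"]}
        categories = {cat["id"]: cat["name"] for cat in doc.get("categories", [])}
        out: dict[str, list[BoundingBox]] = {name: [] for name in images.values()}
        for ann in doc["annotations"]:
            x, y, w, h = ann["bbox"]
            out[images[ann["image_id"]]].append(
                BoundingBox(
                    float(x),
                    float(y),
                    float(x) + float(w),
                    float(y) + float(h),
                    label=categories.get(ann.get("category_id"), "cell"),
                    confidence=ann.get("score"),
                )
            )
    except (KeyError, TypeError) as exc:
        raise AnnotationError(f"{json_path}: not valid COCO JSON ({exc})") from exc
    return out
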