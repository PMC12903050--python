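"""Detection evaluation: IoU, TP/FP/FN matching, precision/recall, AP, studies.

Matching is greedy in descending confidence order (VOC style): each
prediction claims the unmatched ground-truth box of highest IoU, provided
that IoU clears the cutoff (default 0.5).  Average precision is the
all-point interpolated area under the precision-recall curve obtained by
sweeping the confidence cutoff over every distinct confidence value; the
precision at a fixed cutoff (default 0.9) is reported separately because the
two are not the same quantity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .annot_io import BoundingBox, DetectionSet

__all__ = [
    "MatchReport",
    "StudyResult",
    "iou",
    "match_detections",
    "precision_recall",
    "average_precision",
    "precision_at_threshold",
    "pr_curve",
    "run_training_size_study",
    "run_annotator_study",
    "perturb_annotations",
]


@dataclass
class MatchReport:
    """TP/FP/FN bookkeeping for one set of predictions against ground truth."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]]  # (pred index, gt index, IoU)
    iou_threshold: float
    confidence_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        assert self.tp == len(self.pairs)


@dataclass
class StudyResult:
    """Per-condition AP replicates plus summary statistics."""

    condition_label: str
    ap_by_condition: dict = field(default_factory=dict)  # condition -> list[float]

    def mean(self, condition) -> float:
        return float(np.mean(self.ap_by_condition[condition]))

    def sd(self, condition) -> float:
        return float(np.std(self.ap_by_condition[condition], ddof=1)) if len(
            self.ap_by_condition[condition]
        ) > 1 else 0.0

    def summary(self) -> dict:
        return {
            c: {"mean": self.mean(c), "sd": self.sd(c), "n": len(v)}
            for c, v in self.ap_by_condition.items()
        }


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes in continuous coordinates."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def match_detections(
    preds: DetectionSet,
    gts: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
    confidence_threshold: Optional[float] = None,
) -> MatchReport:
    """Greedily match predictions to ground truth at an IoU cutoff.

    Predictions are visited in descending confidence (ties: x_min, then
    y_min); each claims the unmatched GT with the highest IoU if that IoU is
    >= the cutoff (TP), otherwise it is an FP.  Unclaimed GTs are FNs.
    IoU ties between GTs are broken by lower GT index.
    """
    boxes = preds.sorted_boxes()
    if confidence_threshold is not None:
        boxes = [
            b
            for b in boxes
            if b.confidence is not None and b.confidence >= confidence_threshold
        ]
    index_of = {id(b): i for i, b in enumerate(preds.boxes)}
    claimed = [False] * len(gts)
    pairs: list[tuple[int, int, float]] = []
    fp = 0
    for box in boxes:
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if claimed[j]:
                continue
            v = iou(box, gt)
            if v > best_iou:  # strict: ties keep the lower GT index
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            claimed[best_j] = True
            pairs.append((index_of[id(box)], best_j, best_iou))
        else:
            fp += 1
    tp = len(pairs)
    return MatchReport(
        tp=tp,
        fp=fp,
        fn=len(gts) - tp,
        pairs=pairs,
        iou_threshold=iou_threshold,
        confidence_threshold=confidence_threshold,
    )


def precision_recall(report: MatchReport) -> tuple[float, float]:
    """Exact TP/(TP+FP) and TP/(TP+FN); empty denominators default to 1.0."""
    precision = report.tp / (report.tp + report.fp) if report.tp + report.fp else 1.0
    recall = report.tp / (report.tp + report.fn) if report.tp + report.fn else 1.0
    return precision, recall


def _pooled_counts(
    preds_per_image: Sequence[DetectionSet],
    gts_per_image: Sequence[Sequence[BoundingBox]],
    iou_threshold: float,
    confidence_threshold: Optional[float],
) -> tuple[int, int, int]:
    tp = fp = fn = 0
    for preds, gts in zip(preds_per_image, gts_per_image):
        rep = match_detections(preds, gts, iou_threshold, confidence_threshold)
        tp, fp, fn = tp + rep.tp, fp + rep.fp, fn + rep.fn
    return tp, fp, fn


def pr_curve(
    preds_per_image: Sequence[DetectionSet],
    gts_per_image: Sequence[Sequence[BoundingBox]],
    iou_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(precision, recall, cutoff) at every distinct confidence cutoff.

    TP/FP/FN are pooled over all images at each cutoff (per-image matching,
    pooled counts).
    """
    confs = sorted(
        {
            b.confidence
            for det in preds_per_image
            for b in det.boxes
            if b.confidence is not None
        },
        reverse=True,
    )
    if not confs:
        return np.array([]), np.array([]), np.array([])
    ps, rs = [], []
    for c in confs:
        tp, fp, fn = _pooled_counts(preds_per_image, gts_per_image, iou_threshold, c)
        ps.append(tp / (tp + fp) if tp + fp else 1.0)
        rs.append(tp / (tp + fn) if tp + fn else 1.0)
    return np.asarray(ps), np.asarray(rs), np.asarray(confs)


def average_precision(
    preds_per_image: Sequence[DetectionSet],
    gts_per_image: Sequence[Sequence[BoundingBox]],
    iou_threshold: float = 0.5,
) -> float:
    """All-point interpolated area under the pooled precision-recall curve."""
    n_gt = sum(len(g) for g in gts_per_image)
    if n_gt == 0:
        raise ValueError("average_precision undefined with zero ground-truth boxes")
    precision, recall, _ = pr_curve(preds_per_image, gts_per_image, iou_threshold)
    if precision.size == 0:
        return 0.0
    # sort by recall, prepend the (0, p) anchor, integrate the envelope
    order = np.argsort(recall, kind="stable")
    r = np.concatenate([[0.0], recall[order]])
    p = np.concatenate([[precision[order][0]], precision[order]])
    # precision envelope: max precision at recall >= r
    p = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum(np.diff(r) * p[1:]))


def precision_at_threshold(
    preds_per_image: Sequence[DetectionSet],
    gts_per_image: Sequence[Sequence[BoundingBox]],
    confidence_threshold: float = 0.9,
    iou_threshold: float = 0.5,
    per_image: bool = False,
) -> tuple[float, float]:
    """Pooled (default) or per-image-averaged precision/recall at a cutoff."""
    if per_image:
        ps, rs = [], []
        for preds, gts in zip(preds_per_image, gts_per_image):
            rep = match_detections(preds, gts, iou_threshold, confidence_threshold)
            p, r = precision_recall(rep)
            ps.append(p)
            rs.append(r)
        return float(np.mean(ps)), float(np.mean(rs))
    tp, fp, fn = _pooled_counts(
        preds_per_image, gts_per_image, iou_threshold, confidence_threshold
    )
    return (
        tp / (tp + fp) if tp + fp else 1.0,
        tp / (tp + fn) if tp + fn else 1.0,
    )


# ---------------------------------------------------------------------------
# study runners


def perturb_annotations(
    gts_per_image: Sequence[Sequence[BoundingBox]],
    seed: int,
    jitter_px: float = 1.0,
    dilate_px: float = 0.0,
    image_size: Optional[tuple[int, int]] = None,
) -> list[list[BoundingBox]]:
    """Synthetic 'annotator': jitter/dilate ground-truth boxes (stand-in for
    human labeling variability)."""
    rng = np.random.default_rng(seed)
    out: list[list[BoundingBox]] = []
    for gts in gts_per_image:
        row = []
        for b in gts:
            dx, dy = rng.uniform(-jitter_px, jitter_px, size=2)
            nb = BoundingBox(
                b.x_min + dx - dilate_px,
                b.y_min + dy - dilate_px,
                b.x_max + dx + dilate_px,
                b.y_max + dy + dilate_px,
                label=b.label,
            )
            if image_size is not None:
                nb = nb.clipped(*image_size)
            row.append(nb)
        out.append(row)
    return out


def _default_train_eval(train_images, test_images, seed: int, **train_kwargs) -> float:
    from . import detector

    config = detector.TrainConfig(seed=seed, **train_kwargs)
    model, _ = detector.train(train_images, config)
    preds = [detector.infer(model, im.pixels) for im in test_images]
    gts = [im.boxes for im in test_images]
    return average_precision(preds, gts)


def run_training_size_study(
    image_pool: Sequence,
    sizes: Sequence[int],
    test_set: Sequence,
    replicates: int = 5,
    seed: int = 0,
    train_fn: Optional[Callable] = None,
    **train_kwargs,
) -> StudyResult:
    """Train ``replicates`` models per annotation-budget and evaluate each on
    a common held-out test set.

    ``sizes`` are annotation (cell) counts; for each replicate, images are
    drawn randomly from the pool until the annotation budget is covered.
    The pool and the test set must be disjoint.
    """
    if set(map(id, image_pool)) & set(map(id, test_set)):
        raise ValueError("training pool and test set must be disjoint")
    pool_counts = [len(im.boxes) for im in image_pool]
    if max(sizes) > sum(pool_counts):
        raise ValueError(
            f"pool holds {sum(pool_counts)} annotations; largest size "
            f"{max(sizes)} is not coverable"
        )
    train_fn = train_fn or _default_train_eval
    rng = np.random.default_rng(seed)
    result = StudyResult(condition_label="n_annotations")
    for size in sizes:
        aps = []
        for rep in range(replicates):
            order = rng.permutation(len(image_pool))
            subset, n_ann = [], 0
            for idx in order:
                subset.append(image_pool[idx])
                n_ann += pool_counts[idx]
                if n_ann >= size:
                    break
            aps.append(
                float(
                    train_fn(
                        subset,
                        test_set,
                        seed=int(rng.integers(2**31)),
                        **train_kwargs,
                    )
                )
            )
        result.ap_by_condition[size] = aps
    return result


def run_annotator_study(
    annotation_sets: dict,
    images: Sequence,
    test_set: Sequence,
    replicates: int = 5,
    annotations_per_model: int = 40,
    seed: int = 0,
    train_fn: Optional[Callable] = None,
    **train_kwargs,
) -> StudyResult:
    """Per-annotator AP distributions from models trained on each labeling.

    ``annotation_sets`` maps annotator name -> per-image box lists covering
    the *same* images (training labels only; the test set keeps its own
    trusted ground truth).
    """
    if len(annotation_sets) < 2:
        raise ValueError("need >= 2 annotation sets to compare annotators")
    n_images = len(images)
    for name, gts in annotation_sets.items():
        if len(gts) != n_images:
            raise ValueError(
                f"annotator {name!r} covers {len(gts)} images, expected {n_images}"
            )
    train_fn = train_fn or _default_train_eval
    rng = np.random.default_rng(seed)
    result = StudyResult(condition_label="annotator")
    for name, gts in annotation_sets.items():
        relabeled = []
        for im, b in zip(images, gts):
            clone = copy.copy(im)
            clone.boxes = list(b)
            relabeled.append(clone)
        aps = []
        for rep in range(replicates):
            order = rng.permutation(n_images)
            subset, n_ann = [], 0
            for idx in order:
                subset.append(relabeled[idx])
                n_ann += len(relabeled[idx].boxes)
                if n_ann >= annotations_per_model:
                    break
            aps.append(
                float(
                    train_fn(
                        subset,
                        test_set,
                        seed=int(rng.integers(2**31)),
                        **train_kwargs,
                    )
                )
            )
        result.ap_by_condition[name] = aps
    return result
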