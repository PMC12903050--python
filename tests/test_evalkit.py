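import itertools
from fractions import Fraction

import numpy as np
import pytest

from chipcell.annot_io import BoundingBox, DetectionSet
from chipcell.evalkit import (
    MatchReport,
    average_precision,
    iou,
    match_detections,
    perturb_annotations,
    pr_curve,
    precision_at_threshold,
    precision_recall,
    run_annotator_study,
    run_training_size_study,
)

# ---------------------------------------------------------------------------
# independent oracles


def pixel_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Enumerate integer pixels inside each half-open box."""
    pa = {
        (x, y)
        for x in range(int(a.x_min), int(a.x_max))
        for y in range(int(a.y_min), int(a.y_max))
    }
    pb = {
        (x, y)
        for x in range(int(b.x_min), int(b.x_max))
        for y in range(int(b.y_min), int(b.y_max))
    }
    union = len(pa | pb)
    return len(pa & pb) / union if union else 0.0


def optimal_tp(preds, gts, thr) -> int:
    """Brute-force maximum one-to-one matching with IoU >= thr."""
    valid = [[iou(p, g) >= thr for g in gts] for p in preds]
    n_p, n_g = len(preds), len(gts)
    if n_p == 0 or n_g == 0:
        return 0
    best = 0
    big, small, swap = (n_p, n_g, False) if n_p >= n_g else (n_g, n_p, True)
    for perm in itertools.permutations(range(big), small):
        # without swap: perm assigns a GT to each pred; with swap: a pred to
        # each GT
        tp = sum(
            (valid[i][j] if swap else valid[j][i])
            for i, j in enumerate(perm)
        )
        best = max(best, tp)
    return best


def oracle_ap(points) -> float:
    """All-point interpolated area from (precision, recall) points."""
    recalls = sorted({r for _, r in points})
    ap, prev = 0.0, 0.0
    for r in recalls:
        envelope = max(p for p, rr in points if rr >= r)
        ap += (r - prev) * envelope
        prev = r
    return ap


def random_box(rng, span=24, max_side=10) -> BoundingBox:
    x0 = int(rng.integers(0, span - 1))
    y0 = int(rng.integers(0, span - 1))
    return BoundingBox(
        float(x0),
        float(y0),
        float(x0 + rng.integers(1, max_side)),
        float(y0 + rng.integers(1, max_side)),
    )


# ---------------------------------------------------------------------------


class TestIou:
    def test_identical(self):
        b = BoundingBox(2, 3, 9, 11)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(BoundingBox(0, 0, 5, 5), BoundingBox(10, 10, 15, 15)) == 0.0

    def test_half_overlap_hand_value(self):
        # intersection 50, union 150
        v = iou(BoundingBox(0, 0, 10, 10), BoundingBox(5, 0, 15, 10))
        assert v == pytest.approx(50 / 150, rel=1e-12)
        assert v == pytest.approx(
            pixel_iou(BoundingBox(0, 0, 10, 10), BoundingBox(5, 0, 15, 10)), rel=1e-12
        )

    def test_agrees_with_pixel_enumeration(self, rng):
        for _ in range(500):
            a, b = random_box(rng), random_box(rng)
            assert iou(a, b) == pytest.approx(pixel_iou(a, b), rel=1e-9, abs=1e-12)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(2000):
            a, b = random_box(rng), random_box(rng)
            v = iou(a, b)
            assert 0.0 <= v <= 1.0
            assert v == iou(b, a)


class TestMatchDetections:
    def test_exact_hit(self):
        gt = [BoundingBox(0, 0, 10, 10)]
        det = DetectionSet("i", [BoundingBox(0, 0, 10, 10, confidence=0.99)])
        rep = match_detections(det, gt)
        assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0)

    def test_double_detection_one_tp_one_fp(self):
        gt = [BoundingBox(0, 0, 10, 10)]
        det = DetectionSet(
            "i",
            [
                BoundingBox(0, 0, 10, 10, confidence=0.99),
                BoundingBox(1, 1, 11, 11, confidence=0.95),
            ],
        )
        rep = match_detections(det, gt)
        assert (rep.tp, rep.fp, rep.fn) == (1, 1, 0)
        assert rep.pairs[0][0] == 0  # higher confidence claimed the GT

    def test_count_conservation(self, rng):
        for _ in range(200):
            gts = [random_box(rng) for _ in range(rng.integers(0, 6))]
            preds = DetectionSet(
                "i",
                [
                    BoundingBox(
                        b.x_min, b.y_min, b.x_max, b.y_max,
                        confidence=float(rng.uniform(0, 1)),
                    )
                    for b in (random_box(rng) for _ in range(rng.integers(0, 6)))
                ],
            )
            rep = match_detections(preds, gts)
            assert rep.tp + rep.fn == len(gts)
            assert rep.tp + rep.fp == len(preds.boxes)
            assert len({j for _, j, _ in rep.pairs}) == rep.tp  # GTs unique
            assert len({i for i, _, _ in rep.pairs}) == rep.tp  # preds unique

    def test_greedy_le_optimal_mostly_equal(self, rng):
        equal = total = 0
        for _ in range(300):
            n_p, n_g = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            gts = [random_box(rng) for _ in range(n_g)]
            preds = DetectionSet(
                "i",
                [
                    BoundingBox(
                        b.x_min, b.y_min, b.x_max, b.y_max,
                        confidence=float(rng.uniform(0, 1)),
                    )
                    for b in (random_box(rng) for _ in range(n_p))
                ],
            )
            greedy = match_detections(preds, gts, 0.3).tp
            opt = optimal_tp(preds.boxes, gts, 0.3)
            assert greedy <= opt
            total += 1
            equal += greedy == opt
        assert equal / total >= 0.95


class TestPrecisionRecall:
    @pytest.mark.parametrize(
        "tp,fp,fn,p,r",
        [
            (9, 1, 0, 0.9, 1.0),
            (0, 0, 5, 1.0, 0.0),
            (48, 2, 2, 0.96, 0.96),
        ],
    )
    def test_hand_values(self, tp, fp, fn, p, r):
        rep = MatchReport(tp=tp, fp=fp, fn=fn, pairs=[(i, i, 1.0) for i in range(tp)],
                          iou_threshold=0.5)
        assert precision_recall(rep) == (pytest.approx(p), pytest.approx(r))

    def test_exact_ratios_50_random_reports(self, rng):
        for _ in range(50):
            tp = int(rng.integers(0, 30))
            fp = int(rng.integers(0, 30))
            fn = int(rng.integers(0, 30))
            rep = MatchReport(tp=tp, fp=fp, fn=fn,
                              pairs=[(i, i, 1.0) for i in range(tp)],
                              iou_threshold=0.5)
            p, r = precision_recall(rep)
            exp_p = Fraction(tp, tp + fp) if tp + fp else Fraction(1)
            exp_r = Fraction(tp, tp + fn) if tp + fn else Fraction(1)
            assert p == float(exp_p) and r == float(exp_r)


def _random_instances(rng, n_images=3):
    preds, gts = [], []
    for i in range(n_images):
        g = [random_box(rng) for _ in range(rng.integers(1, 5))]
        p = []
        for b in g:
            if rng.uniform() < 0.8:  # jittered hit
                dx, dy = rng.uniform(-2, 2, size=2)
                p.append(
                    BoundingBox(
                        b.x_min + dx, b.y_min + dy, b.x_max + dx, b.y_max + dy,
                        confidence=float(rng.uniform(0.4, 1.0)),
                    )
                )
        for _ in range(rng.integers(0, 3)):  # false positives
            b = random_box(rng)
            p.append(
                BoundingBox(
                    b.x_min, b.y_min, b.x_max, b.y_max,
                    confidence=float(rng.uniform(0, 0.9)),
                )
            )
        preds.append(DetectionSet(f"img{i}", p))
        gts.append(g)
    return preds, gts


class TestAveragePrecision:
    def test_perfect_detector(self, rng):
        gts = [[random_box(rng) for _ in range(3)] for _ in range(4)]
        preds = [
            DetectionSet(
                f"i{k}",
                [
                    BoundingBox(b.x_min, b.y_min, b.x_max, b.y_max, confidence=0.99)
                    for b in g
                ],
            )
            for k, g in enumerate(gts)
        ]
        assert average_precision(preds, gts) == pytest.approx(1.0)

    def test_all_false_positives(self):
        gts = [[BoundingBox(0, 0, 5, 5)]]
        preds = [DetectionSet("i", [BoundingBox(50, 50, 60, 60, confidence=0.9)])]
        assert average_precision(preds, gts) == 0.0

    def test_zero_gt_raises(self):
        with pytest.raises(ValueError):
            average_precision([DetectionSet("i", [])], [[]])

    def test_hand_constructed_three_preds_two_gts(self):
        gts = [[BoundingBox(0, 0, 10, 10), BoundingBox(20, 0, 30, 10)]]
        preds = [
            DetectionSet(
                "i",
                [
                    BoundingBox(0, 0, 10, 10, confidence=0.9),   # TP
                    BoundingBox(40, 40, 50, 50, confidence=0.8),  # FP
                    BoundingBox(20, 0, 30, 10, confidence=0.7),   # TP
                ],
            )
        ]
        # cutoffs: 0.9 -> P1 R1/2; 0.8 -> P1/2 R1/2; 0.7 -> P2/3 R1
        points = [(1.0, 0.5), (0.5, 0.5), (2 / 3, 1.0)]
        assert average_precision(preds, gts) == pytest.approx(oracle_ap(points))
        assert average_precision(preds, gts) == pytest.approx(
            0.5 * 1.0 + 0.5 * (2 / 3)
        )

    def test_matches_sweep_oracle_on_random_instances(self, rng):
        for _ in range(100):
            preds, gts = _random_instances(rng)
            ps, rs, _ = pr_curve(preds, gts)
            expected = oracle_ap(list(zip(ps, rs)))
            assert average_precision(preds, gts) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_box_order_with_tied_confidences(self, rng):
        preds, gts = _random_instances(rng)
        # force ties
        for det in preds:
            det.boxes = [
                BoundingBox(b.x_min, b.y_min, b.x_max, b.y_max,
                            confidence=round(b.confidence, 1))
                for b in det.boxes
            ]
        shuffled = [
            DetectionSet(d.image_id, list(reversed(d.boxes))) for d in preds
        ]
        assert average_precision(preds, gts) == average_precision(shuffled, gts)


class TestPrecisionAtThreshold:
    def test_pooled_vs_per_image_flag(self, rng):
        preds, gts = _random_instances(rng, n_images=4)
        pooled = precision_at_threshold(preds, gts, 0.5)
        averaged = precision_at_threshold(preds, gts, 0.5, per_image=True)
        assert all(0 <= v <= 1 for v in pooled + averaged)


# ---------------------------------------------------------------------------
# study runners (stub trainer keeps these fast; the real-detector versions
# live in the acceptance suite)


def _stub_train_fn(quality_by_size):
    def fn(train_images, test_images, seed, **_):
        n_ann = sum(len(im.boxes) for im in train_images)
        base = quality_by_size(n_ann)
        return base + np.random.default_rng(seed).normal(0, 0.01)

    return fn


class _FakeImage:
    def __init__(self, n_boxes):
        self.boxes = [BoundingBox(0, 0, 5, 5)] * n_boxes
        self.pixels = np.zeros((4, 4))


def test_training_size_study_structure():
    pool = [_FakeImage(4) for _ in range(20)]
    test = [_FakeImage(4) for _ in range(5)]
    res = run_training_size_study(
        pool, sizes=[1, 16], test_set=test, replicates=3, seed=0,
        train_fn=_stub_train_fn(lambda n: min(1.0, 0.1 + 0.02 * n)),
    )
    assert set(res.ap_by_condition) == {1, 16}
    assert all(len(v) == 3 for v in res.ap_by_condition.values())
    assert res.mean(16) > res.mean(1)


def test_training_size_study_rejects_overlap():
    pool = [_FakeImage(2) for _ in range(5)]
    with pytest.raises(ValueError, match="disjoint"):
        run_training_size_study(pool, [1], test_set=pool[:1], replicates=1,
                                train_fn=_stub_train_fn(lambda n: 0.5))


def test_training_size_study_rejects_oversized_budget():
    pool = [_FakeImage(1) for _ in range(3)]
    with pytest.raises(ValueError, match="coverable"):
        run_training_size_study(pool, [100], test_set=[_FakeImage(1)], replicates=1,
                                train_fn=_stub_train_fn(lambda n: 0.5))


def test_annotator_study_needs_two_sets():
    imgs = [_FakeImage(3) for _ in range(4)]
    with pytest.raises(ValueError, match=">= 2"):
        run_annotator_study({"A": [im.boxes for im in imgs]}, imgs,
                            test_set=[_FakeImage(1)], replicates=1)


def test_annotator_study_mismatched_coverage():
    imgs = [_FakeImage(3) for _ in range(4)]
    sets = {"A": [im.boxes for im in imgs], "B": [imgs[0].boxes]}
    with pytest.raises(ValueError, match="covers"):
        run_annotator_study(sets, imgs, test_set=[_FakeImage(1)], replicates=1)


def test_annotator_study_identical_sets_same_distribution():
    imgs = [_FakeImage(3) for _ in range(6)]
    gts = [im.boxes for im in imgs]
    res = run_annotator_study(
        {"A": gts, "B": gts}, imgs, test_set=[_FakeImage(1)], replicates=3,
        annotations_per_model=6, seed=0,
        train_fn=lambda tr, te, seed, **_: 0.9 + 0.001 * sum(len(i.boxes) for i in tr),
    )
    assert res.ap_by_condition["A"] == res.ap_by_condition["B"]


def test_perturb_annotations_jitters_within_bounds(rng):
    gts = [[random_box(rng) for _ in range(4)] for _ in range(3)]
    out = perturb_annotations(gts, seed=1, jitter_px=1.0, image_size=(40, 40))
    for orig_row, new_row in zip(gts, out):
        for o, p in zip(orig_row, new_row):
            assert abs(o.x_min - p.x_min) <= 1.0 + 1e-9
            assert 0 <= p.x_min < p.x_max <= 40
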