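"""IoU matching and macro-averaged detection metrics."""

import itertools

import numpy as np
import pytest

import seedxray as sx
from seedxray.errors import ConfigurationError, ParameterError
from seedxray.evaluate import ClassCounts


def det(box, score=0.9):
    return sx.Detection(box=box, label=box.label, score=score)


class TestIou:
    def test_self_overlap_is_one(self):
        b = sx.Box(3, 7, 40, 50, "M")
        assert sx.iou(b, b) == 1.0

    def test_disjoint_is_zero(self):
        assert sx.iou(sx.Box(0, 0, 10, 10, "M"),
                      sx.Box(20, 20, 30, 30, "M")) == 0.0

    def test_half_overlap_arithmetic(self):
        a = sx.Box(0, 0, 10, 10, "M")
        b = sx.Box(5, 0, 15, 10, "M")
        assert sx.iou(a, b) == pytest.approx(1 / 3)

    def test_touching_edges_no_overlap(self):
        # half-open: [0,10) and [10,20) share no pixel
        assert sx.iou(sx.Box(0, 0, 10, 10, "M"),
                      sx.Box(10, 0, 20, 10, "M")) == 0.0


class TestMatchDetections:
    def test_perfect_predictions(self):
        gt = [sx.Box(0, 0, 10, 10, "M"), sx.Box(20, 20, 40, 40, "N")]
        counts = sx.match_detections(gt, [det(b) for b in gt])
        assert counts.get("M") == (1, 0, 0)
        assert counts.get("N") == (1, 0, 0)

    def test_cross_class_confusion_is_fp_plus_fn(self):
        # a perfectly localized detection with the wrong class never matches
        gt = [sx.Box(0, 0, 10, 10, "M")]
        wrong = sx.Detection(box=sx.Box(0, 0, 10, 10, "E"), label="E",
                             score=0.99)
        counts = sx.match_detections(gt, [wrong])
        assert counts.get("E") == (0, 1, 0)
        assert counts.get("M") == (0, 0, 1)

    def test_greedy_once_only_duplicate_detection(self):
        gt = [sx.Box(0, 0, 10, 10, "M")]
        d1 = sx.Detection(box=sx.Box(0, 0, 10, 10, "M"), label="M", score=0.9)
        d2 = sx.Detection(box=sx.Box(1, 0, 11, 10, "M"), label="M", score=0.8)
        counts = sx.match_detections(gt, [d1, d2])
        assert counts.get("M") == (1, 1, 0)
        # order in the input list does not matter, only the score
        counts2 = sx.match_detections(gt, [d2, d1])
        assert counts2.get("M") == (1, 1, 0)

    def test_tp_plus_fn_equals_ground_truth_count(self, rng):
        for _ in range(30):
            gt, dets, labels = _random_instance(rng)
            counts = sx.match_detections(gt, dets)
            for label in labels:
                tp, _, fn = counts.get(label)
                assert tp + fn == sum(1 for b in gt if b.label == label)

    def test_greedy_within_factor_two_of_optimal(self, rng):
        """Brute-force assignment oracle: optimal TP via exhaustive matching.

        Greedy matching never exceeds the optimum and is at least half of
        it; on these small instances it agrees with the optimum almost
        always — discrepancies are counted and bounded.
        """
        disagreements = 0
        for _ in range(40):
            gt, dets, _ = _random_instance(rng, max_boxes=5)
            counts = sx.match_detections(gt, dets)
            greedy_tp = sum(counts.tp.values())
            best = _optimal_tp(gt, dets)
            assert greedy_tp <= best
            assert greedy_tp >= int(np.ceil(best / 2))
            if greedy_tp != best:
                disagreements += 1
        assert disagreements <= 4

    def test_invalid_threshold(self):
        with pytest.raises(ParameterError):
            sx.match_detections([], [], iou_threshold=0.0)


def _random_instance(rng, max_boxes=6, size=100):
    labels = ["M", "N"]
    def random_box():
        x0 = int(rng.integers(0, size - 12))
        y0 = int(rng.integers(0, size - 12))
        w = int(rng.integers(6, 13))
        h = int(rng.integers(6, 13))
        return sx.Box(x0, y0, x0 + w, y0 + h, str(rng.choice(labels)))

    gt = [random_box() for _ in range(int(rng.integers(1, max_boxes + 1)))]
    dets = []
    for _ in range(int(rng.integers(0, max_boxes + 1))):
        base = gt[int(rng.integers(len(gt)))]
        dx, dy = (int(v) for v in rng.integers(-4, 5, 2))
        x0 = max(0, base.x_min + dx)
        y0 = max(0, base.y_min + dy)
        box = sx.Box(x0, y0, x0 + base.width, y0 + base.height,
                     str(rng.choice(labels)))
        dets.append(sx.Detection(box=box, label=box.label,
                                 score=float(rng.uniform(0.1, 1.0))))
    return gt, dets, labels


def _optimal_tp(gt, dets, iou_threshold=0.5):
    """Maximum TP over all one-to-one class-consistent assignments."""
    feasible = [
        [j for j, g in enumerate(gt)
         if g.label == d.label and sx.iou(g, d.box) >= iou_threshold]
        for d in dets
    ]

    best = 0
    def search(i, used, tp):
        nonlocal best
        if tp + (len(dets) - i) <= best:
            return
        if i == len(dets):
            best = max(best, tp)
            return
        for j in feasible[i]:
            if j not in used:
                search(i + 1, used | {j}, tp + 1)
        search(i + 1, used, tp)

    search(0, frozenset(), 0)
    return best


class TestMacroMetrics:
    def test_equal_weight_average(self):
        counts = ClassCounts(tp={"A": 2, "B": 1}, fp={"A": 0, "B": 1},
                             fn={"A": 0, "B": 0})
        report = sx.macro_metrics(counts)
        assert report.macro_precision == pytest.approx(75.0)

    def test_f1_fixed_point_when_p_equals_r(self):
        counts = ClassCounts(tp={"A": 3}, fp={"A": 1}, fn={"A": 1})
        report = sx.macro_metrics(counts)
        assert report.macro_precision == report.macro_recall
        assert report.macro_f1 == pytest.approx(report.macro_precision)

    def test_hand_worked_two_class_example(self):
        counts = ClassCounts(tp={"A": 3, "B": 2}, fp={"A": 1, "B": 0},
                             fn={"A": 0, "B": 2})
        report = sx.macro_metrics(counts, classes=["A", "B"])
        assert report.macro_precision == pytest.approx(87.5)
        assert report.macro_recall == pytest.approx(75.0)
        assert report.macro_f1 == pytest.approx(2 * 87.5 * 75 / 162.5)
        assert report.macro_f1 == pytest.approx(80.769, abs=1e-3)

    def test_zero_denominator_contributes_zero_with_warning(self, caplog):
        counts = ClassCounts(tp={"A": 1, "B": 0}, fp={"A": 0, "B": 0},
                             fn={"A": 0, "B": 3})
        with caplog.at_level("WARNING", logger="seedxray.evaluate"):
            report = sx.macro_metrics(counts)
        assert report.macro_precision == pytest.approx(50.0)
        assert "no predictions" in caplog.text

    def test_k_mismatch_rejected(self):
        counts = ClassCounts(tp={"A": 1}, fp={}, fn={})
        with pytest.raises(ConfigurationError):
            sx.macro_metrics(counts, classes=3)
        with pytest.raises(ConfigurationError):
            sx.macro_metrics(counts, classes=["B"])

    def test_macro_f1_between_macro_precision_and_recall(self, rng):
        # the harmonic mean always lies between its two arguments
        for _ in range(20):
            tp = {c: int(rng.integers(1, 20)) for c in "AB"}
            fp = {c: int(rng.integers(0, 10)) for c in "AB"}
            fn = {c: int(rng.integers(0, 10)) for c in "AB"}
            report = sx.macro_metrics(ClassCounts(tp, fp, fn))
            lo = min(report.macro_precision, report.macro_recall)
            hi = max(report.macro_precision, report.macro_recall)
            assert lo - 1e-9 <= report.macro_f1 <= hi + 1e-9


class TestEvaluateDataset:
    def _gt(self):
        return {
            "img0": [sx.Box(0, 0, 10, 10, "M"), sx.Box(30, 30, 44, 44, "N")],
            "img1": [sx.Box(5, 5, 20, 20, "N")],
        }

    def test_empty_detections_all_zero(self):
        report, per_image = sx.evaluate_dataset(self._gt(), {})
        assert report.macro_precision == 0.0
        assert report.macro_recall == 0.0
        assert report.macro_f1 == 0.0
        assert per_image["fn"].sum() == 3

    def test_split_halves_additive(self):
        gt = self._gt()
        dets = {k: [det(b) for b in v] for k, v in gt.items()}
        dets["img1"] = []  # make img1 all-FN so halves differ
        joint, _ = sx.evaluate_dataset(gt, dets)
        half_a = sx.match_detections(gt["img0"], dets["img0"])
        half_b = sx.match_detections(gt["img1"], [])
        summed = half_a.add(half_b)
        for name in joint.counts.classes():
            assert joint.counts.get(name) == summed.get(name)

    def test_unknown_image_id_rejected(self):
        dets = {"nope": [det(sx.Box(0, 0, 5, 5, "M"))]}
        with pytest.raises(ConfigurationError, match="nope"):
            sx.evaluate_dataset(self._gt(), dets)

    def test_detection_frame_round_trip(self):
        import pandas as pd
        gt = self._gt()
        rows = [dict(image_id=k, label=b.label, score=0.8,
                     x_min=b.x_min, y_min=b.y_min, x_max=b.x_max,
                     y_max=b.y_max)
                for k, v in gt.items() for b in v]
        report, _ = sx.evaluate_dataset(gt, pd.DataFrame(rows))
        assert report.macro_f1 == pytest.approx(100.0)
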