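"""Pixel metrics, confusion matrices, macro-F1, instance matching."""

import numpy as np
import pytest

from dabquant import (
    InstanceMask,
    StainClass,
    class_confusion,
    macro_f1,
    matched_instance_f1,
    pixel_metrics,
)
from dabquant.errors import ParameterError, ShapeError


def _brute_force(pred, gt):
    tp = fp = fn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p and g:
            tp += 1
        elif p:
            fp += 1
        elif g:
            fn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    iou = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    return precision, recall, f1, iou


class TestPixelMetrics:
    def test_identical_masks_are_perfect(self):
        m = np.zeros((6, 6), bool)
        m[2:5, 2:5] = True
        assert pixel_metrics(m, m) == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint_masks_are_zero(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0] = True
        b[5, 5] = True
        with pytest.warns(UserWarning):
            assert pixel_metrics(a, b) == (0.0, 0.0, 0.0, 0.0)

    def test_half_overlap_case(self):
        gt = np.ones((10, 10), bool)
        pred = np.zeros((10, 10), bool)
        pred[:, :5] = True
        precision, recall, f1, iou = pixel_metrics(pred, gt)
        assert precision == 1.0
        assert recall == 0.5
        assert f1 == pytest.approx(2 / 3)
        assert iou == 0.5

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(100):
            pred = rng.random((8, 8)) > 0.5
            gt = rng.random((8, 8)) > 0.5
            expected = _brute_force(pred, gt)
            got = pixel_metrics(pred, gt)
            assert got == pytest.approx(expected)

    def test_iou_never_exceeds_f1(self, rng):
        for _ in range(100):
            pred = rng.random((8, 8)) > 0.3
            gt = rng.random((8, 8)) > 0.7
            _, _, f1, iou = pixel_metrics(pred, gt)
            assert iou <= f1 + 1e-12
            if f1 not in (0.0, 1.0):
                assert iou < f1

    def test_f1_harmonic_mean_identity(self, rng):
        for _ in range(20):
            pred = rng.random((8, 8)) > 0.4
            gt = rng.random((8, 8)) > 0.6
            p, r, f1, _ = pixel_metrics(pred, gt)
            if p + r > 0:
                assert f1 * (p + r) == pytest.approx(2 * p * r)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            pixel_metrics(np.zeros((4, 4), bool), np.zeros((4, 5), bool))


class TestClassConfusion:
    def test_perfect_prediction_is_diagonal(self):
        classes = ["Strong", "Moderate", "Weak", "Negative", "Weak"]
        conf = class_confusion(classes, classes)
        assert conf.sum() == 5
        assert np.all(conf == np.diag(np.diag(conf)))

    def test_single_misclassification_off_diagonal(self):
        conf = class_confusion(["Moderate"], ["Weak"])
        assert conf[2, 1] == 1  # row = gt Weak, col = pred Moderate
        assert conf.sum() == 1

    def test_order_invariance(self, rng):
        names = [c.value for c in StainClass]
        pred = list(rng.choice(names, 30))
        gt = list(rng.choice(names, 30))
        perm = rng.permutation(30)
        a = class_confusion(pred, gt)
        b = class_confusion([pred[i] for i in perm], [gt[i] for i in perm])
        assert np.array_equal(a, b)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            class_confusion(["Strongish"], ["Weak"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            class_confusion(["Weak"], [])


class TestMacroF1:
    def test_perfect_diagonal_is_one(self):
        conf = np.diag([5, 4, 3, 2])
        macro, per_class = macro_f1(conf)
        assert macro == 1.0
        assert all(v["f1"] == 1.0 for v in per_class.values())

    def test_two_class_balanced_matrix(self):
        conf = np.zeros((4, 4), dtype=int)
        conf[0, 0], conf[0, 1] = 8, 2
        conf[1, 0], conf[1, 1] = 2, 8
        with pytest.warns(UserWarning, match="absent"):
            macro_all, per_class = macro_f1(conf)
        assert per_class[StainClass.STRONG]["f1"] == pytest.approx(0.8)
        assert per_class[StainClass.MODERATE]["f1"] == pytest.approx(0.8)
        # fixed 4-class denominator: absent classes count as 0 ...
        assert macro_all == pytest.approx(0.4)
        # ... while present_only averages the populated classes
        with pytest.warns(UserWarning, match="absent"):
            macro_present, _ = macro_f1(conf, present_only=True)
        assert macro_present == pytest.approx(0.8)

    def test_fully_misclassified_class_drags_macro_down(self):
        conf = np.diag([5, 5, 5, 0])
        conf[3, 0] = 5  # all Negative predicted Strong
        macro, per_class = macro_f1(conf)
        assert per_class[StainClass.NEGATIVE]["f1"] == 0.0
        others = [per_class[c]["f1"] for c in list(StainClass)[:3]]
        assert macro < np.mean(others)

    def test_class_relabeling_equivariance(self, rng):
        conf = rng.integers(0, 10, (4, 4))
        perm = rng.permutation(4)
        macro_a, _ = macro_f1(conf)
        macro_b, _ = macro_f1(conf[np.ix_(perm, perm)])
        assert macro_a == pytest.approx(macro_b)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ParameterError):
            macro_f1(np.zeros((4, 4), dtype=int))


class TestInstanceMatching:
    def test_identical_masks_give_perfect_instance_f1(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[2:8, 2:8] = 1
        labels[12:18, 12:18] = 2
        m = InstanceMask(labels=labels)
        assert matched_instance_f1(m, m) == (1.0, 1.0, 1.0)

    def test_missed_object_costs_recall(self):
        gt = np.zeros((20, 20), dtype=np.int32)
        gt[2:8, 2:8] = 1
        gt[12:18, 12:18] = 2
        pred = np.where(gt == 1, 1, 0).astype(np.int32)
        precision, recall, f1 = matched_instance_f1(InstanceMask(labels=pred), InstanceMask(labels=gt))
        assert precision == 1.0
        assert recall == 0.5
        assert f1 == pytest.approx(2 / 3)

    def test_low_iou_pair_not_matched(self):
        gt = np.zeros((10, 10), dtype=np.int32)
        gt[0:2, 0:10] = 1  # 20 px
        pred = np.zeros((10, 10), dtype=np.int32)
        pred[0:1, 0:2] = 1  # 2 px, IoU = 2/20 = 0.1
        with pytest.warns(UserWarning):
            _, _, f1 = matched_instance_f1(InstanceMask(labels=pred), InstanceMask(labels=gt))
        assert f1 == 0.0
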