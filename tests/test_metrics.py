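"""One-vs-rest metrics, overlap scores, ROC/AUC, report assembly."""

import numpy as np
import pytest

from ihsnet.metrics import (
    ConfusionMatrix,
    auc_pair_count,
    build_report,
    classification_metrics,
    f1_from_precision_recall,
    icc_2_1,
    macro_mean,
    one_vs_rest_counts,
    roc_auc,
    round_report,
    segmentation_scores,
)


class TestOneVsRest:
    def test_two_class_worked_example(self):
        cm = ConfusionMatrix(np.array([[3, 1], [2, 4]]))
        assert one_vs_rest_counts(cm, 0) == (3, 2, 4, 1)  # TP, FP, TN, FN

    def test_perfect_diagonal_has_no_errors(self):
        cm = ConfusionMatrix(np.diag([5, 3, 7, 2, 4]))
        for c in range(5):
            tp, fp, tn, fn = one_vs_rest_counts(cm, c)
            assert fp == 0 and fn == 0

    def test_counts_partition_total(self):
        rng = np.random.default_rng(0)
        cm = ConfusionMatrix(rng.integers(0, 20, (5, 5)))
        for c in range(5):
            assert sum(one_vs_rest_counts(cm, c)) == cm.total

    def test_out_of_range_class_rejected(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int))
        with pytest.raises(IndexError):
            one_vs_rest_counts(cm, 3)


class TestClassificationMetrics:
    def test_sah_row_f1_rounds_to_080(self):
        assert round_report(f1_from_precision_recall(0.67, 1.00)) == 0.80

    def test_sdh_row_f1_rounds_to_090(self):
        assert round_report(f1_from_precision_recall(1.00, 0.82)) == 0.90

    def test_all_correct_gives_all_ones(self):
        m = classification_metrics(tp=10, fp=0, tn=40, fn=0)
        assert (m.accuracy, m.precision, m.specificity, m.sensitivity, m.f1) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_zero_denominators_reported_as_zero_with_flag(self):
        m = classification_metrics(tp=0, fp=0, tn=5, fn=0)
        assert m.precision == 0.0 and m.sensitivity == 0.0
        assert "precision" in m.undefined and "sensitivity" in m.undefined

    def test_f1_is_harmonic_mean_of_precision_and_recall(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fp, fn = rng.integers(1, 30, 3)
            m = classification_metrics(int(tp), int(fp), 10, int(fn))
            assert m.f1 == pytest.approx(
                f1_from_precision_recall(m.precision, m.sensitivity)
            )


class TestSegmentationScores:
    def test_identical_masks_score_one(self):
        m = np.random.default_rng(0).integers(0, 6, (16, 16))
        for dice, iou in segmentation_scores(m, m).values():
            assert dice == 1.0 and iou == 1.0

    def test_half_overlap_worked_example(self):
        # |A| = |B| = 4, overlap 2: Dice 0.5, IoU 2/6
        a = np.zeros((4, 4), int); a[0, :4] = 1
        b = np.zeros((4, 4), int); b[0, 2:] = 1; b[1, :2] = 1
        dice, iou = segmentation_scores(a, b, classes=[1])[1]
        assert dice == pytest.approx(0.5)
        assert iou == pytest.approx(2 / 6)

    def test_iou_dice_algebraic_identity(self):
        # IoU = D / (2 - D) for any mask pair
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.integers(0, 3, (12, 12))
            b = rng.integers(0, 3, (12, 12))
            for dice, iou in segmentation_scores(a, b, classes=[1, 2]).values():
                assert iou == pytest.approx(dice / (2.0 - dice))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segmentation_scores(np.zeros((4, 4), int), np.zeros((5, 5), int))


class TestMacroMean:
    def test_reference_dice_row_means_to_079(self):
        assert round_report(macro_mean([0.77, 0.80, 0.92, 0.64, 0.84])) == 0.79

    def test_reference_iou_row_means_to_068(self):
        assert round_report(macro_mean([0.67, 0.71, 0.82, 0.51, 0.69])) == 0.68

    def test_constant_list_is_its_own_mean(self):
        assert macro_mean([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_order_invariance(self):
        vals = [0.1, 0.9, 0.5, 0.2]
        assert macro_mean(vals) == pytest.approx(macro_mean(vals[::-1]))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            macro_mean([])


def test_round_report_is_half_up():
    assert round_report(0.125) == 0.13
    assert round_report(0.794) == 0.79
    assert round_report(0.795) == 0.80


class TestRocAuc:
    def test_perfect_separation_scores_one(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        truths = np.array([0, 0, 1, 1])
        aucs = roc_auc(scores, truths)
        assert aucs[0] == pytest.approx(1.0) and aucs[1] == pytest.approx(1.0)

    def test_inverted_scores_give_zero(self):
        scores = np.array([[0.1], [0.9]])
        padded = np.hstack([scores, 1 - scores])
        truths = np.array([0, 1])
        assert roc_auc(padded, truths)[0] == pytest.approx(0.0)

    def test_four_sample_toy_pair_count(self):
        # exhaustive pair count: pairs (0.9 > 0.8), (0.9 > 0.1),
        # (0.3 < 0.8), (0.3 > 0.1) -> 3/4
        scores = np.array([0.9, 0.8, 0.3, 0.1])
        labels = np.array([1, 0, 1, 0])
        assert auc_pair_count(scores, labels) == pytest.approx(0.75)
        two_col = np.column_stack([1 - scores, scores])
        assert roc_auc(two_col, labels)[1] == pytest.approx(0.75)

    def test_trapezoid_equals_pair_count_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(6, 30))
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            expected = auc_pair_count(scores, labels)
            got = roc_auc(np.column_stack([1 - scores, scores]), labels)[1]
            assert got == pytest.approx(expected)

    def test_degenerate_class_flagged_nan(self):
        scores = np.array([[0.5, 0.5], [0.4, 0.6]])
        truths = np.array([1, 1])
        assert np.isnan(roc_auc(scores, truths)[0])


def test_icc_two_way_random_single_measure():
    # perfect agreement between raters -> ICC 1
    ratings = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
    assert icc_2_1(ratings) == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    noisy = ratings + rng.normal(0, 5.0, ratings.shape)
    assert icc_2_1(noisy) < 0.9


def test_build_report_shapes_and_rounding():
    truths = np.array([0, 1, 2, 3, 4, 0, 1])
    preds = np.array([0, 1, 2, 3, 3, 0, 1])
    rng = np.random.default_rng(0)
    scores = rng.random((7, 5))
    scores /= scores.sum(axis=1, keepdims=True)
    names = ["EDH", "IPH", "IVH", "SAH", "SDH"]
    dice = {n: 0.7 for n in names}
    iou = {n: 0.55 for n in names}
    report = build_report(truths, preds, scores, dice, iou, names)
    assert report.macro_dice == 0.70 and report.macro_iou == 0.55
    assert set(report.per_class) == set(names)
    assert report.per_class["SDH"]["recall"] == 0.0  # the one SDH sample missed
    assert np.array(report.confusion).sum() == 7
    assert "ovr_accuracy" in report.per_class["EDH"]
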