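"""Focal loss, Dice coefficient/loss and the combined objective."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihsnet.losses import (
    MultiTaskLoss,
    dice_coefficient,
    dice_loss,
    dice_loss_grad,
    focal_loss,
    focal_loss_grad,
    multitask_loss,
)
from ihsnet.metrics import classification_metrics
from ihsnet.nn import softmax


class TestFocalLoss:
    def test_perfect_prediction_has_zero_loss(self):
        assert focal_loss(np.array([0.0, 1.0, 0.0]), 1) == pytest.approx(0.0)

    def test_gamma_zero_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(0)
        probs = softmax(rng.normal(size=(20, 5)), axis=1)
        truths = rng.integers(0, 5, 20)
        fl = focal_loss(probs, truths, gamma=0.0, alpha=1.0)
        ce = float(np.mean(-np.log(probs[np.arange(20), truths])))
        assert fl == pytest.approx(ce, rel=1e-12)

    def test_half_probability_worked_example(self):
        # -1 * (1-0.5)^2 * ln 0.5 = 0.25 ln 2
        loss = focal_loss(np.array([0.5, 0.5]), 0, gamma=2.0, alpha=1.0)
        assert loss == pytest.approx(0.25 * math.log(2.0), rel=1e-12)

    @given(st.floats(min_value=0.01, max_value=0.98))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_monotonically_decreasing_in_true_probability(self, p):
        lo = focal_loss(np.array([p, 1 - p]), 0, gamma=2.0, alpha=0.25)
        hi = focal_loss(np.array([p + 0.01, 1 - p - 0.01]), 0, gamma=2.0, alpha=0.25)
        assert hi < lo

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(4, 5))
        truths = np.array([0, 2, 4, 1])
        _, grad = focal_loss_grad(softmax(z, axis=1), truths)
        eps = 1e-6
        for idx in [(0, 0), (1, 2), (3, 4)]:
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            fd = (
                focal_loss(softmax(zp, axis=1), truths)
                - focal_loss(softmax(zm, axis=1), truths)
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestDiceCoefficient:
    def test_identical_masks_score_one(self):
        m = (np.random.default_rng(0).random((16, 16)) > 0.5).astype(int)
        assert dice_coefficient(m, m) == pytest.approx(1.0)

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((8, 8)); a[:4] = 1
        b = np.zeros((8, 8)); b[4:] = 1
        assert dice_coefficient(a, b) == pytest.approx(0.0)

    def test_half_overlap_worked_example(self):
        # |A| = |B| = 4, |A ∩ B| = 2 -> 2*2 / 8 = 0.5
        a = np.zeros((4, 4)); a[0, :4] = 1
        b = np.zeros((4, 4)); b[0, 2:] = 1; b[1, :2] = 1
        assert dice_coefficient(a, b) == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = (rng.random((12, 12)) > 0.6).astype(int)
        b = (rng.random((12, 12)) > 0.6).astype(int)
        assert dice_coefficient(a, b) == pytest.approx(dice_coefficient(b, a))

    def test_empty_vs_empty_defined_as_one(self):
        z = np.zeros((5, 5))
        assert dice_coefficient(z, z) == pytest.approx(1.0)

    def test_dice_equals_pixel_f1(self):
        # Dice on binary masks is identically the F1 of the pixel
        # confusion matrix
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = (rng.random((10, 10)) > rng.random()).astype(int)
            b = (rng.random((10, 10)) > rng.random()).astype(int)
            if a.sum() + b.sum() == 0:
                continue
            tp = int((a & b).sum())
            fp = int((b & ~a.astype(bool)).sum())
            fn = int((a & ~b.astype(bool)).sum())
            tn = a.size - tp - fp - fn
            f1 = classification_metrics(tp, fp, tn, fn).f1
            assert dice_coefficient(a, b) == pytest.approx(f1)


class TestDiceLoss:
    def _one_hot_probs(self, labels, c=6):
        n, h, w = labels.shape
        p = np.zeros((n, c, h, w))
        for k in range(c):
            p[:, k][labels == k] = 1.0
        return p

    def test_perfect_prediction_loss_near_zero(self):
        labels = np.random.default_rng(0).integers(0, 6, (2, 16, 16))
        loss = dice_loss(self._one_hot_probs(labels), labels, smooth=0.0)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_fully_wrong_prediction_loss_near_one(self):
        # every pixel predicted as the next class over: zero overlap in
        # every foreground class that occurs
        labels = np.random.default_rng(1).integers(1, 6, (1, 8, 8))
        pred = np.roll(self._one_hot_probs(labels), shift=1, axis=1)
        loss = dice_loss(pred, labels, smooth=0.0, mode="batch")
        assert loss == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["image", "batch"])
    def test_gradient_matches_finite_differences(self, mode):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(2, 6, 6, 6))
        labels = rng.integers(0, 6, (2, 6, 6))
        _, grad = dice_loss_grad(softmax(z, axis=1), labels, mode=mode)
        eps = 1e-6
        for idx in [(0, 1, 2, 3), (1, 5, 0, 0), (0, 0, 4, 4)]:
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            lp = dice_loss(softmax(zp, axis=1), labels, mode=mode)
            lm = dice_loss(softmax(zm, axis=1), labels, mode=mode)
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-9)


class TestMultiTaskLoss:
    def test_lambda_zero_leaves_only_focal_term(self):
        rng = np.random.default_rng(0)
        seg = softmax(rng.normal(size=(2, 6, 8, 8)), axis=1)
        cls = softmax(rng.normal(size=(2, 5)), axis=1)
        labels = rng.integers(0, 6, (2, 8, 8))
        truths = np.array([0, 3])
        loss = multitask_loss(cls, seg, truths, labels, lam=0.0)
        assert loss.total == pytest.approx(loss.l_fl)

    def test_total_is_exact_weighted_sum(self):
        loss = MultiTaskLoss(l_fl=0.2, l_ms=0.3, lam=1.0)
        assert loss.total == pytest.approx(0.5)

    def test_nonnegative_on_random_batches(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            seg = softmax(rng.normal(size=(3, 6, 8, 8)), axis=1)
            cls = softmax(rng.normal(size=(3, 5)), axis=1)
            labels = rng.integers(0, 6, (3, 8, 8))
            truths = rng.integers(0, 5, 3)
            lam = float(rng.uniform(0, 3))
            assert multitask_loss(cls, seg, truths, labels, lam=lam).total >= 0.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            multitask_loss(
                np.full((1, 5), 0.2), np.full((1, 6, 4, 4), 1 / 6),
                np.array([0]), np.zeros((1, 4, 4), dtype=int), lam=-1.0,
            )
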