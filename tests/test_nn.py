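"""Layer library: batch norm, activations, convolution gradients."""

import numpy as np
import pytest

from ihsnet.nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    LeakyReLU,
    Linear,
    Upsample2x,
    batchnorm_apply,
    leaky_relu,
    relu,
    softmax,
)


class TestBatchNorm:
    def test_scale_invariance(self):
        # normalizing the pre-activation makes the output independent of
        # any positive rescaling of the incoming weights
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 3, 8, 8))
        for a in (10.0, 0.01, 3.7):
            assert np.allclose(batchnorm_apply(x), batchnorm_apply(a * x), atol=1e-4)

    def test_already_normalized_input_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2000, 3))
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        assert np.allclose(batchnorm_apply(x), x, atol=1e-4)

    def test_channel_means_equal_beta_shift(self):
        rng = np.random.default_rng(2)
        x = rng.normal(loc=5.0, scale=2.0, size=(8, 4, 6, 6))
        beta = np.array([0.0, 1.0, -2.0, 0.5])
        y = batchnorm_apply(x, gamma=np.ones(4), beta=beta)
        assert np.allclose(y.mean(axis=(0, 2, 3)), beta, atol=1e-6)

    def test_layer_running_stats_track_batches(self):
        bn = BatchNorm2d(2, momentum=0.5)
        x = np.random.default_rng(3).normal(loc=3.0, size=(16, 2, 4, 4)).astype(np.float32)
        for _ in range(30):
            bn.forward(x, train=True)
        eval_out = bn.forward(x, train=False)
        train_out = bn.forward(x, train=True)
        assert np.allclose(eval_out, train_out, atol=1e-2)

    def test_zero_variance_channel_guarded_by_epsilon(self):
        x = np.ones((4, 1, 2, 2))
        y = batchnorm_apply(x)
        assert np.isfinite(y).all()


class TestActivations:
    def test_relu_and_leaky_semantics(self):
        x = np.array([-2.0, -0.5, 0.0, 1.5])
        assert np.array_equal(relu(x), [0.0, 0.0, 0.0, 1.5])
        assert np.allclose(leaky_relu(x, 0.001), [-0.002, -0.0005, 0.0, 1.5])

    def test_leaky_layer_backward_scales_negative_side(self):
        layer = LeakyReLU(0.001)
        x = np.array([[-1.0, 2.0]], dtype=np.float32)
        layer.forward(x, train=True)
        dx = layer.backward(np.ones_like(x))
        assert np.allclose(dx, [[0.001, 1.0]])

    def test_softmax_rows_sum_to_one(self):
        z = np.random.default_rng(0).normal(size=(7, 5)) * 50
        assert np.allclose(softmax(z, axis=1).sum(axis=1), 1.0, atol=1e-6)


class TestConvAndLinear:
    def test_conv_stride2_halves_spatial_size(self):
        conv = Conv2d(3, 8, kernel=3, stride=2, rng=np.random.default_rng(0))
        y = conv.forward(np.zeros((1, 3, 16, 16), dtype=np.float32))
        assert y.shape == (1, 8, 8, 8)

    def test_conv_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        conv = Conv2d(2, 3, kernel=3, stride=2, rng=rng)
        x = rng.random((2, 2, 8, 8)).astype(np.float32)
        w = rng.random((2, 3, 4, 4)).astype(np.float32)
        conv.forward(x, train=True)
        dx = conv.backward(w.copy())
        eps = 1e-2
        idx = (1, 4)
        orig = conv.weight.value[idx]
        conv.weight.value[idx] = orig + eps
        lp = float((w * conv.forward(x)).sum())
        conv.weight.value[idx] = orig - eps
        lm = float((w * conv.forward(x)).sum())
        conv.weight.value[idx] = orig
        assert conv.weight.grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-2)
        xidx = (0, 1, 3, 3)
        xp, xm = x.copy(), x.copy()
        xp[xidx] += eps
        xm[xidx] -= eps
        fd = ((w * conv.forward(xp)).sum() - (w * conv.forward(xm)).sum()) / (2 * eps)
        assert dx[xidx] == pytest.approx(fd, rel=1e-2)

    def test_linear_backward_transposes_forward(self):
        rng = np.random.default_rng(2)
        lin = Linear(4, 3, rng=rng)
        x = rng.random((5, 4)).astype(np.float32)
        lin.forward(x, train=True)
        dy = rng.random((5, 3)).astype(np.float32)
        dx = lin.backward(dy)
        assert np.allclose(dx, dy @ lin.weight.value, atol=1e-6)


class TestUpsample:
    @pytest.mark.parametrize("mode", ["bilinear", "nearest"])
    def test_doubles_spatial_size(self, mode):
        up = Upsample2x(mode)
        y = up.forward(np.zeros((1, 2, 5, 7), dtype=np.float32))
        assert y.shape == (1, 2, 10, 14)

    def test_nearest_replicates_pixels(self):
        up = Upsample2x("nearest")
        x = np.arange(4, dtype=np.float32).reshape(1, 1, 2, 2)
        y = up.forward(x)
        expected = [[0, 0, 1, 1], [0, 0, 1, 1], [2, 2, 3, 3], [2, 2, 3, 3]]
        assert np.array_equal(y[0, 0], expected)

    def test_bilinear_preserves_constants(self):
        up = Upsample2x("bilinear")
        y = up.forward(np.full((1, 1, 4, 4), 3.5, dtype=np.float32))
        assert np.allclose(y, 3.5)

    def test_backward_is_adjoint_of_forward(self):
        # <A x, y> must equal <x, A^T y> for the linear upsampling map
        rng = np.random.default_rng(0)
        up = Upsample2x("bilinear")
        x = rng.random((1, 1, 6, 6)).astype(np.float32)
        y = rng.random((1, 1, 12, 12)).astype(np.float32)
        ax = up.forward(x, train=True)
        aty = up.backward(y)
        assert float((ax * y).sum()) == pytest.approx(float((x * aty).sum()), rel=1e-5)


def test_adam_minimizes_quadratic():
    from ihsnet.nn import Param

    p = Param(np.array([5.0, -3.0]))
    opt = Adam([p], lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        p.grad[...] = 2 * p.value
        opt.step()
    assert np.allclose(p.value, 0.0, atol=1e-3)
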