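"""Unit tests for the NumPy layer library against brute-force oracles."""

import numpy as np
import pytest

from msfanet.nn import (Adam, BatchNorm2d, ConfigError, Conv2d, Dense,
                        Dropout, Param, ShapeError)
from oracles import conv2d_oracle, finite_difference_grads


@pytest.mark.parametrize("kernel,dilation", [
    ((1, 1), 1), ((3, 3), 1), ((1, 3), 1), ((3, 1), 1),
    ((3, 3), 2), ((3, 3), 3), ((3, 3), 6), ((3, 3), 12), ((3, 3), 18),
])
def test_conv_matches_loop_oracle(rng, kernel, dilation):
    """Every kernel shape / dilation agrees with a direct sliding-window
    convolution written as explicit loops over taps."""
    conv = Conv2d(2, 3, kernel, dilation, rng=rng, dtype=np.float64)
    conv.bias.data = rng.normal(size=3)
    x = rng.normal(size=(2, 8, 8, 2))
    got = conv.forward(x)
    want = conv2d_oracle(x, conv.weight.data, conv.bias.data, dilation)
    assert got.shape == want.shape == (2, 8, 8, 3)
    np.testing.assert_allclose(got, want, atol=1e-5)


def test_conv_single_channel_rate3_matches_oracle(rng):
    """8x8 single-channel input at tap spacing 3 equals the loop oracle."""
    conv = Conv2d(1, 1, (3, 3), dilation=3, rng=rng, dtype=np.float64)
    x = rng.normal(size=(1, 8, 8, 1))
    np.testing.assert_allclose(
        conv.forward(x), conv2d_oracle(x, conv.weight.data, conv.bias.data, 3),
        atol=1e-5)


def test_dilation_equals_zero_interleaved_dense_kernel(rng):
    """A rate-2 3x3 convolution equals a standard 5x5 convolution whose
    interior taps are zero (tap-equivalence of the dilation convention)."""
    conv = Conv2d(2, 2, (3, 3), dilation=2, rng=rng, dtype=np.float64)
    dense = np.zeros((5, 5, 2, 2))
    dense[::2, ::2] = conv.weight.data
    x = rng.normal(size=(1, 10, 10, 2))
    np.testing.assert_allclose(
        conv.forward(x), conv2d_oracle(x, dense, conv.bias.data, dilation=1),
        atol=1e-10)


@pytest.mark.parametrize("shape", [(1, 5, 7, 3), (2, 16, 16, 3), (1, 1, 1, 3)])
def test_conv_preserves_spatial_dims(rng, shape):
    conv = Conv2d(3, 4, (3, 3), dilation=3, rng=rng)
    out = conv.forward(rng.normal(size=shape).astype(np.float32))
    assert out.shape == shape[:3] + (4,)


def test_conv_zero_input_zero_bias_gives_zero(rng):
    conv = Conv2d(3, 4, (3, 3), rng=rng)
    out = conv.forward(np.zeros((1, 6, 6, 3), dtype=np.float32))
    assert np.all(out == 0)


def test_conv_invalid_configs():
    with pytest.raises(ConfigError):
        Conv2d(3, 4, (3, 3), dilation=0)
    with pytest.raises(ConfigError):
        Conv2d(3, 4, (2, 2))
    conv = Conv2d(3, 4, (3, 3))
    with pytest.raises(ShapeError):
        conv.forward(np.zeros((1, 6, 6, 2), dtype=np.float32))


def test_batchnorm_identity_stats_then_relu_is_relu(rng):
    """With running mean 0 / var 1 and default affine, inference-mode BN is
    the identity (up to epsilon), so BN + ReLU reduces to ReLU."""
    bn = BatchNorm2d(3, dtype=np.float64)
    x = rng.normal(size=(2, 4, 4, 3))
    out = np.maximum(bn.forward(x, train=False), 0)
    np.testing.assert_allclose(out, np.maximum(x, 0), atol=1e-4)
    assert np.all(out >= 0)


def test_batchnorm_standardizes_channel():
    """A channel holding {1, 2, 3} standardizes to +-sqrt(3/2), 0 before the
    affine transform (hand arithmetic: std of {1,2,3} is sqrt(2/3))."""
    bn = BatchNorm2d(1, dtype=np.float64)
    x = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1)
    out = bn.forward(x, train=True)
    expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
    np.testing.assert_allclose(out[:, 0, 0, 0], expected, atol=1e-4)
    assert abs(out.mean()) < 1e-12
    np.testing.assert_allclose(out.std(), 1.0, atol=1e-4)


def test_batchnorm_zero_variance_is_stabilized():
    bn = BatchNorm2d(1, dtype=np.float64)
    out = bn.forward(np.full((4, 2, 2, 1), 7.0), train=True)
    assert np.isfinite(out).all()


@pytest.mark.parametrize("layer_name", ["conv", "conv_dilated", "bn", "dense"])
def test_layer_gradients_match_finite_differences(rng, layer_name):
    """Hand-written backward passes agree with central differences."""
    x = rng.normal(size=(2, 5, 5, 3))
    if layer_name == "conv":
        layer = Conv2d(3, 2, (3, 3), rng=rng, dtype=np.float64)
    elif layer_name == "conv_dilated":
        layer = Conv2d(3, 2, (3, 3), dilation=2, rng=rng, dtype=np.float64)
    elif layer_name == "bn":
        layer = BatchNorm2d(3, dtype=np.float64)
        layer.gamma.data = rng.normal(size=3)
        layer.beta.data = rng.normal(size=3)
    else:
        layer = Dense(3, 2, rng=rng, dtype=np.float64)
        x = rng.normal(size=(4, 3))
    proj = rng.normal(size=layer.forward(x, train=True).shape)

    def loss_fn():
        return float((layer.forward(x, train=True) * proj).sum())

    layer.zero_grad()
    layer.forward(x, train=True)
    layer.backward(proj)
    arrays = {n: p.data for n, p in layer.named_parameters()}
    grads = {n: p.grad.copy() for n, p in layer.named_parameters()}
    for name, entries in finite_difference_grads(loss_fn, arrays).items():
        for idx, num in entries:
            assert grads[name].ravel()[idx] == pytest.approx(num, rel=1e-4,
                                                             abs=1e-7)


def test_conv_input_gradient_matches_finite_differences(rng):
    conv = Conv2d(2, 2, (3, 3), dilation=2, rng=rng, dtype=np.float64)
    x = rng.normal(size=(1, 5, 5, 2))
    proj = rng.normal(size=(1, 5, 5, 2))
    conv.forward(x, train=True)
    gx = conv.backward(proj)

    def loss_fn():
        return float((conv.forward(x, train=True) * proj).sum())

    for (idx, num) in finite_difference_grads(loss_fn, {"x": x},
                                              indices_per_array=5)["x"]:
        assert gx.ravel()[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


def test_dropout_eval_is_identity_and_train_preserves_scale(rng):
    drop = Dropout(0.5, rng=rng)
    x = np.ones((1, 50, 50, 4), dtype=np.float64)
    assert drop.forward(x, train=False) is x
    out = drop.forward(x, train=True)
    kept = out[out != 0]
    np.testing.assert_allclose(kept, 2.0)          # inverted scaling
    assert out.mean() == pytest.approx(1.0, abs=0.05)
    assert Dropout(0.0).forward(x, train=True) is x


def test_dropout_invalid_rate():
    with pytest.raises(ConfigError):
        Dropout(1.0)


def test_adam_reduces_simple_quadratic(rng):
    p = Param(np.array([5.0, -3.0]))
    opt = Adam([p])
    for _ in range(300):
        p.grad = 2 * p.data
        opt.step(0.1)
    np.testing.assert_allclose(p.data, 0.0, atol=1e-3)
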