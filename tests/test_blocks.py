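"""Tests of the architecture blocks: attention, encoder, bridge, decoder,
and the composed network."""

import numpy as np
import pytest

from msfanet.blocks import (ASCSBridge, Decoder, DilatedBranch, MSFANet,
                            MSFEncoder, SCSE, count_parameters,
                            multiply_accumulates, parameter_breakdown)
from msfanet.config import LossWeights, ModelConfig
from msfanet.losses import composite_loss
from msfanet.nn import ConfigError, Conv2d, ShapeError
from oracles import bn_eval_oracle, conv2d_oracle, finite_difference_grads, scse_oracle


# ---------------------------------------------------------------- scSE
def test_scse_matches_loop_oracle(rng):
    scse = SCSE(4, reduction=2, rng=rng, dtype=np.float64)
    x = rng.normal(size=(2, 4, 4, 4))
    want = scse_oracle(x, scse.fc1.weight.data, scse.fc1.bias.data,
                       scse.fc2.weight.data, scse.fc2.bias.data,
                       scse.spatial.weight.data, scse.spatial.bias.data)
    np.testing.assert_allclose(scse.forward(x), want, atol=1e-6)


def test_scse_zero_input_gives_zero(rng):
    scse = SCSE(4, rng=rng)
    out = scse.forward(np.zeros((1, 3, 3, 4), dtype=np.float32))
    assert np.all(out == 0)


def test_scse_output_bounded_by_twice_input(rng):
    """Both gates lie in (0,1) and combine additively, so |out| <= 2|in|."""
    scse = SCSE(8, rng=rng)
    x = rng.normal(size=(2, 6, 6, 8)).astype(np.float32)
    out = scse.forward(x)
    assert np.all(np.abs(out) <= 2 * np.abs(x) + 1e-6)


def test_scse_rejects_channels_below_reduction():
    with pytest.raises(ConfigError):
        SCSE(1, reduction=2)


# ---------------------------------------------------------------- encoder
def test_dilated_branch_rate1_uses_1x1_kernel_and_preserves_dims(rng):
    branch = DilatedBranch(3, 16, rate=1, rng=rng)
    assert branch.sample.kh == branch.sample.kw == 1
    out = branch.forward(rng.normal(size=(1, 12, 12, 3)).astype(np.float32))
    assert out.shape == (1, 12, 12, 16)
    branch5 = DilatedBranch(3, 4, rate=5, rng=rng)
    assert branch5.sample.dilation == 5
    assert branch5.forward(
        rng.normal(size=(1, 12, 12, 3)).astype(np.float32)).shape == (1, 12, 12, 4)


def test_dilated_branch_rejects_nonpositive_rate():
    with pytest.raises(ConfigError):
        DilatedBranch(3, 4, rate=0)


def test_msf_concatenates_five_branches_to_5G_channels(rng):
    enc = MSFEncoder(3, 128, (1, 3, 6, 12, 18), scse_placement="II", rng=rng)
    out = enc.forward(rng.normal(size=(1, 8, 8, 3)).astype(np.float32))
    assert out.shape == (1, 8, 8, 640)          # 5 branches x G=128


def test_msf_single_branch_equals_that_branch(rng):
    """With one branch and no attention, the encoder is the branch."""
    enc = MSFEncoder(3, 4, (2,), scse_placement="none", rng=rng,
                     dtype=np.float64)
    x = rng.normal(size=(1, 8, 8, 3))
    np.testing.assert_array_equal(enc.forward(x), enc.branch0.forward(x))


def test_msf_attention_saturates_to_doubled_branches(rng):
    """As the scSE gate logits go to +inf both gates saturate at 1, and the
    additive combine converges to twice the ungated map."""
    enc_plain = MSFEncoder(3, 4, (1, 2, 3, 4, 5), scse_placement="none",
                           rng=np.random.default_rng(5), dtype=np.float64)
    enc_gated = MSFEncoder(3, 4, (1, 2, 3, 4, 5), scse_placement="I",
                           rng=np.random.default_rng(5), dtype=np.float64)
    # same init seed and creation order -> identical branch weights
    for i in range(5):
        gate = getattr(enc_gated, f"scse_pre{i}")
        gate.fc2.weight.data[:] = 0
        gate.fc2.bias.data[:] = 60.0       # sigmoid(60) ~ 1
        gate.spatial.weight.data[:] = 0
        gate.spatial.bias.data[:] = 60.0
    x = rng.normal(size=(1, 6, 6, 3))
    np.testing.assert_allclose(enc_gated.forward(x), 2 * enc_plain.forward(x),
                               rtol=1e-6, atol=1e-9)


def test_msf_config_requires_five_rates():
    with pytest.raises(ConfigError):
        ModelConfig(rates=(1, 3, 6))


# ---------------------------------------------------------------- bridge
def test_ascs_zero_input_gives_zero_under_either_rule(rng):
    for rule in ("literal_product", "sum_product"):
        bridge = ASCSBridge(3, 3, fusion_rule=rule, dropout_rate=0.0, rng=rng)
        out = bridge.forward(np.zeros((1, 6, 6, 3), dtype=np.float32))
        assert np.all(out == 0)


def test_asymmetric_pair_is_two_thirds_of_square_kernel():
    """1x3 + 3x1 kernels together hold 2/3 the weights of one 3x3 kernel:
    the 33% parameter reduction of asymmetric convolution."""
    c = 7
    square = Conv2d(c, c, (3, 3), bias=False).weight.size
    pair = (Conv2d(c, c, (1, 3), bias=False).weight.size
            + Conv2d(c, c, (3, 1), bias=False).weight.size)
    assert pair * 3 == square * 2


@pytest.mark.parametrize("rule", ["literal_product", "sum_product"])
def test_ascs_matches_stepwise_oracle(rng, rule):
    """The bridge equals conv -> BN -> ReLU per path (loop oracles) plus the
    configured fusion arithmetic, in inference mode."""
    bridge = ASCSBridge(3, 3, fusion_rule=rule, dropout_rate=0.0, rng=rng,
                        dtype=np.float64)
    x = rng.normal(size=(1, 8, 8, 3))

    def path(p):
        y = conv2d_oracle(x, p.conv.weight.data, p.conv.bias.data)
        y = bn_eval_oracle(y, p.bn.running_mean, p.bn.running_var,
                           p.bn.gamma.data, p.bn.beta.data)
        return np.maximum(y, 0)

    c = path(bridge.path_square)
    a = path(bridge.path_horizontal)
    b = path(bridge.path_vertical)
    want = (a * c) * (b * c) if rule == "literal_product" else (a + c) * (b + c)
    np.testing.assert_allclose(bridge.forward(x), want, atol=1e-5)


def test_ascs_rejects_unknown_fusion_rule():
    with pytest.raises(ConfigError):
        ASCSBridge(3, 3, fusion_rule="mean")


def test_ascs_dropout_off_at_inference(rng):
    bridge = ASCSBridge(3, 3, dropout_rate=0.5, rng=rng)
    x = rng.normal(size=(1, 6, 6, 3)).astype(np.float32)
    np.testing.assert_array_equal(bridge.forward(x), bridge.forward(x))


# ---------------------------------------------------------------- decoder
def test_decoder_bridge_of_ones_leaves_compressed_unchanged(rng):
    dec = Decoder(6, 3, rng=rng, dtype=np.float64)
    encoded = rng.normal(size=(1, 4, 4, 6))
    feats = dec.forward(encoded, np.ones((1, 4, 4, 3)))
    np.testing.assert_array_equal(feats.calibrated, feats.compressed)


def test_decoder_matches_stepwise_oracle(rng):
    dec = Decoder(6, 3, rng=rng, dtype=np.float64)
    encoded = rng.normal(size=(1, 4, 4, 6))
    bridge = rng.normal(size=(1, 4, 4, 3))
    feats = dec.forward(encoded, bridge)
    comp = np.maximum(bn_eval_oracle(
        conv2d_oracle(encoded, dec.compress.weight.data, dec.compress.bias.data),
        dec.compress_bn.running_mean, dec.compress_bn.running_var,
        dec.compress_bn.gamma.data, dec.compress_bn.beta.data), 0)
    np.testing.assert_allclose(feats.compressed, comp, atol=1e-5)
    np.testing.assert_allclose(feats.calibrated, comp * bridge, atol=1e-5)
    fused = np.concatenate([bridge, comp, comp * bridge], axis=3)
    assert feats.fused.shape == (1, 4, 4, 9)
    logit = bn_eval_oracle(
        conv2d_oracle(fused, dec.out_conv.weight.data, dec.out_conv.bias.data),
        dec.out_bn.running_mean, dec.out_bn.running_var,
        dec.out_bn.gamma.data, dec.out_bn.beta.data)
    np.testing.assert_allclose(feats.prediction, 1 / (1 + np.exp(-logit)),
                               atol=1e-5)


def test_decoder_spatial_mismatch_raises(rng):
    dec = Decoder(6, 3, rng=rng)
    with pytest.raises(ShapeError):
        dec.forward(np.zeros((1, 4, 4, 6), dtype=np.float32),
                    np.zeros((1, 5, 5, 3), dtype=np.float32))


# ---------------------------------------------------------------- network
def test_full_forward_shapes_and_probability_range(tiny_config, rng):
    model = MSFANet(tiny_config)
    x = rng.normal(size=(2, 16, 16, 3)).astype(np.float32)
    feats = model.forward(x)
    assert feats.prediction.shape == (2, 16, 16, 1)
    assert np.all(feats.prediction > 0) and np.all(feats.prediction < 1)
    assert feats.bridge.shape == feats.compressed.shape == feats.calibrated.shape
    assert len(feats.aux) == 3
    for aux in feats.aux:
        assert aux.shape == feats.prediction.shape


def test_batch_predictions_preserve_order(tiny_config, rng):
    model = MSFANet(tiny_config)
    x = rng.normal(size=(3, 8, 8, 3)).astype(np.float32)
    batched = model.forward(x).prediction
    singles = [model.forward(x[i:i + 1]).prediction[0] for i in range(3)]
    for i in range(3):
        np.testing.assert_allclose(batched[i], singles[i], atol=1e-6)


def test_inference_is_bit_identical(tiny_config, rng):
    model = MSFANet(tiny_config)
    x = rng.normal(size=(1, 8, 8, 3)).astype(np.float32)
    np.testing.assert_array_equal(model.forward(x).prediction,
                                  model.forward(x).prediction)


def test_every_parameter_receives_a_gradient(tiny_config, tiny_batch):
    """One backward pass from the composite loss leaves a finite, mostly
    nonzero gradient on every trainable parameter of every block."""
    model = MSFANet(tiny_config)
    x, y = tiny_batch
    model.zero_grad()
    model.forward(x, train=True)
    model.backward_from_labels(y.astype(np.float32), LossWeights())
    n_nonzero = 0
    names = list(dict(model.named_parameters()))
    assert any(n.startswith("encoder") for n in names)
    assert any(n.startswith("bridge") for n in names)
    assert any(n.startswith("decoder") for n in names)
    assert any(n.startswith("head_") for n in names)
    for name, p in model.named_parameters():
        assert np.isfinite(p.grad).all(), name
        n_nonzero += int(np.any(p.grad != 0))
    assert n_nonzero >= 0.9 * len(names)


def test_full_network_gradient_check(tiny_config, rng):
    """Sampled finite-difference check of the composite-loss gradients
    through encoder, bridge, decoder and all auxiliary heads."""
    model = MSFANet(tiny_config, dtype=np.float64)
    x = rng.normal(size=(2, 6, 6, 3))
    y = (rng.random((2, 6, 6, 1)) < 0.4).astype(np.float64)
    w = LossWeights(0.5, 0.3, 0.2)

    def loss_fn():
        return composite_loss(model.forward(x, train=True), y, w)

    model.zero_grad()
    model.forward(x, train=True)
    model.backward_from_labels(y, w)
    analytic = {n: p.grad.copy() for n, p in model.named_parameters()}
    arrays = {n: p.data for n, p in model.named_parameters()}
    for name, entries in finite_difference_grads(
            loss_fn, arrays, indices_per_array=2).items():
        for idx, num in entries:
            assert analytic[name].ravel()[idx] == pytest.approx(
                num, rel=1e-3, abs=1e-7), name


def test_forward_rejects_bad_inputs(tiny_config):
    model = MSFANet(tiny_config)
    with pytest.raises(ShapeError):
        model.forward(np.zeros((1, 8, 8, 4), dtype=np.float32))
    with pytest.raises(ValueError):
        model.forward(np.full((1, 8, 8, 3), np.nan, dtype=np.float32))


# ---------------------------------------------------------------- counting
def test_count_parameters_closed_forms():
    assert Conv2d(1, 1, (3, 3), bias=False).num_parameters() == 9
    assert (Conv2d(1, 1, (1, 3), bias=False).num_parameters()
            + Conv2d(1, 1, (3, 1), bias=False).num_parameters()) == 6


def test_parameter_breakdown_sums_to_total(tiny_config):
    model = MSFANet(tiny_config)
    breakdown = parameter_breakdown(model)
    total = breakdown.pop("total")
    assert sum(breakdown.values()) == total == count_parameters(model)


def test_branch_conv_parameters_scale_with_width():
    """Doubling G multiplies the dominant (G->G) filter-conv weights by 4."""
    b1 = DilatedBranch(3, 8, rate=3)
    b2 = DilatedBranch(3, 16, rate=3)
    assert b2.filter.weight.size == 4 * b1.filter.weight.size


def test_multiply_accumulates_scales_with_resolution(tiny_config):
    model = MSFANet(tiny_config)
    m1 = multiply_accumulates(model, (16, 16))
    m2 = multiply_accumulates(model, (32, 32))
    # dense (pooled) terms are resolution independent; conv terms scale by 4
    assert m1 < m2 < 4 * m1
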