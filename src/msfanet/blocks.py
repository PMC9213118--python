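"""The segmentation network as composable, shape-checked blocks.

The network is an encoder–decoder that never changes spatial resolution:

* **MSF encoder** — five parallel branches over the RGB input: one 1x1
  convolution (global, pixel-wise) and four 3x3 dilated convolutions at
  increasing rates, each followed by a conventional 3x3 filtering
  convolution, batch norm and ReLU.  Branch outputs (G channels each) are
  concatenated on the channel axis into a 5G-channel map; scSE attention can
  gate each branch ("I"), the concatenated map ("II"), or both.
* **ASCS bridge** — an asymmetric skip connection from the input to the
  decoder: parallel 3x3, 1x3 and 3x1 convolution+BN+ReLU paths fused
  element-wise (Hadamard) into a narrow (3-channel) map, then dropout.
* **Calibrating decoder** — compresses the encoder map with a 1x1
  convolution to the bridge width, calibrates it by pixel-wise
  multiplication with the bridge map, concatenates bridge + compressed +
  calibrated, and maps the result to a single-channel sigmoid probability
  map.

Auxiliary 1x1-convolution + sigmoid heads on the bridge, compressed and
calibrated maps provide deep supervision during training.

All blocks implement a hand-written ``backward``; the full network exposes
``backward_from_labels`` which seeds every sigmoid head with the fused
sigmoid/cross-entropy gradient (p - y) / n_pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .nn import (Adam, BatchNorm2d, ConfigError, Conv2d, Dense, Dropout,
                 Module, Param, ReLU, ShapeError, Sigmoid, sigmoid)

__all__ = [
    "DilatedBranch",
    "SCSE",
    "MSFEncoder",
    "ASCSBridge",
    "Decoder",
    "AuxHead",
    "MSFANet",
    "DecoderFeatures",
    "count_parameters",
    "parameter_breakdown",
    "build_model",
]


@dataclass
class DecoderFeatures:
    """All decoder-stage maps of one forward pass (NHWC arrays).

    ``bridge`` is the fused skip map, ``compressed`` the channel-reduced
    encoder map, ``calibrated`` their pixel-wise product, ``fused`` their
    channel concatenation, ``prediction`` the single-channel probability map
    and ``aux`` the three auxiliary-head probability maps (bridge,
    compressed, calibrated order).
    """

    bridge: np.ndarray
    compressed: np.ndarray
    calibrated: np.ndarray
    fused: np.ndarray
    prediction: np.ndarray
    aux: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None


class ConvBNReLU(Module):
    """conv -> batch norm -> ReLU, spatial-size preserving."""

    def __init__(self, in_ch, out_ch, kernel, dilation=1, rng=None, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, dilation, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(out_ch, dtype=dtype)
        self.act = ReLU()

    def forward(self, x, train=False):
        return self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.act.backward(g)))


class DilatedBranch(Module):
    """One encoder branch: 1x1 (rate 1) or dilated 3x3 sampling convolution,
    then a conventional 3x3 filtering convolution, batch norm and ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rate: int, rng=None, dtype=np.float32):
        super().__init__()
        if rate < 1:
            raise ConfigError(f"branch rate must be >= 1, got {rate}")
        self.rate = rate
        kernel = (1, 1) if rate == 1 else (3, 3)
        self.sample = Conv2d(in_ch, out_ch, kernel, dilation=1 if rate == 1 else rate,
                             rng=rng, dtype=dtype)
        self.filter = Conv2d(out_ch, out_ch, (3, 3), rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(out_ch, dtype=dtype)
        self.act = ReLU()

    def forward(self, x, train=False):
        y = self.sample.forward(x, train)
        y = self.filter.forward(y, train)
        return self.act.forward(self.bn.forward(y, train), train)

    def backward(self, g):
        g = self.bn.backward(self.act.backward(g))
        return self.sample.backward(self.filter.backward(g))


class SCSE(Module):
    """Concurrent spatial and channel squeeze-and-excitation attention.

    Channel branch: global average pool -> bottleneck dense (reduction r) ->
    ReLU -> expansion dense -> sigmoid gate, applied channel-wise.  Spatial
    branch: 1x1 convolution to one channel -> sigmoid gate, applied
    pixel-wise.  The two recalibrated maps are combined by addition.
    """

    def __init__(self, channels: int, reduction: int = 2, rng=None, dtype=np.float32):
        super().__init__()
        if channels < reduction:
            raise ConfigError(
                f"scSE needs channels >= reduction, got {channels} < {reduction}")
        hidden = max(channels // reduction, 1)
        self.fc1 = Dense(channels, hidden, rng=rng, dtype=dtype)
        self.fc_act = ReLU()
        self.fc2 = Dense(hidden, channels, rng=rng, dtype=dtype)
        self.spatial = Conv2d(channels, 1, (1, 1), rng=rng, dtype=dtype)
        self._cache = None

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        z = x.mean(axis=(1, 2))                       # squeeze (N, C)
        s = sigmoid(self.fc2.forward(
            self.fc_act.forward(self.fc1.forward(z, train), train), train))
        q = sigmoid(self.spatial.forward(x, train))   # (N, H, W, 1)
        out = x * s[:, None, None, :] + x * q
        self._cache = (x, s, q) if train else None
        return out

    def backward(self, g):
        x, s, q = self._cache
        n, h, w, c = x.shape
        gx = g * s[:, None, None, :] + g * q
        # channel gate path
        gs = (g * x).sum(axis=(1, 2)) * s * (1 - s)
        gz = self.fc1.backward(self.fc_act.backward(self.fc2.backward(gs)))
        gx += gz[:, None, None, :] / (h * w)
        # spatial gate path
        gq = (g * x).sum(axis=3, keepdims=True) * q * (1 - q)
        gx += self.spatial.backward(gq)
        return gx


class MSFEncoder(Module):
    """Multiscale-fusion encoder: parallel dilated branches concatenated on
    channels, with optional scSE attention per branch and/or after fusion."""

    def __init__(self, in_ch: int, branch_channels: int, rates,
                 scse_placement: str = "II", scse_reduction: int = 2,
                 rng=None, dtype=np.float32):
        super().__init__()
        self.rates = tuple(rates)
        self.branch_channels = branch_channels
        self.placement = scse_placement
        for i, rate in enumerate(self.rates):
            setattr(self, f"branch{i}",
                    DilatedBranch(in_ch, branch_channels, rate, rng=rng, dtype=dtype))
        if scse_placement in ("I", "I_and_II"):
            for i in range(len(self.rates)):
                setattr(self, f"scse_pre{i}",
                        SCSE(branch_channels, scse_reduction, rng=rng, dtype=dtype))
        if scse_placement in ("II", "I_and_II"):
            self.scse_post = SCSE(branch_channels * len(self.rates),
                                  scse_reduction, rng=rng, dtype=dtype)

    @property
    def out_channels(self) -> int:
        return self.branch_channels * len(self.rates)

    def forward(self, x, train=False):
        feats = []
        for i in range(len(self.rates)):
            f = getattr(self, f"branch{i}").forward(x, train)
            if self.placement in ("I", "I_and_II"):
                f = getattr(self, f"scse_pre{i}").forward(f, train)
            feats.append(f)
        y = np.concatenate(feats, axis=3)
        if self.placement in ("II", "I_and_II"):
            y = self.scse_post.forward(y, train)
        return y

    def backward(self, g):
        if self.placement in ("II", "I_and_II"):
            g = self.scse_post.backward(g)
        gc = self.branch_channels
        gx = None
        for i in range(len(self.rates)):
            gi = g[..., i * gc:(i + 1) * gc]
            if self.placement in ("I", "I_and_II"):
                gi = getattr(self, f"scse_pre{i}").backward(gi)
            gb = getattr(self, f"branch{i}").backward(gi)
            gx = gb if gx is None else gx + gb
        return gx


class ASCSBridge(Module):
    """Asymmetric skip connection: parallel 3x3 / 1x3 / 3x1 conv+BN+ReLU
    paths fused element-wise, then dropout.

    ``literal_product`` fuses as (Y1x3 * Y3x3) * (Y3x1 * Y3x3);
    ``sum_product`` as (Y1x3 + Y3x3) * (Y3x1 + Y3x3).
    """

    def __init__(self, in_ch: int, out_ch: int, fusion_rule: str = "literal_product",
                 dropout_rate: float = 0.1, rng=None,
                 dropout_rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if fusion_rule not in ("literal_product", "sum_product"):
            raise ConfigError(f"unknown fusion_rule {fusion_rule!r}")
        self.fusion_rule = fusion_rule
        self.path_square = ConvBNReLU(in_ch, out_ch, (3, 3), rng=rng, dtype=dtype)
        self.path_horizontal = ConvBNReLU(in_ch, out_ch, (1, 3), rng=rng, dtype=dtype)
        self.path_vertical = ConvBNReLU(in_ch, out_ch, (3, 1), rng=rng, dtype=dtype)
        self.dropout = Dropout(dropout_rate, rng=dropout_rng)
        self._cache = None

    def forward(self, x, train=False):
        c = self.path_square.forward(x, train)    # 3x3
        a = self.path_horizontal.forward(x, train)  # 1x3
        b = self.path_vertical.forward(x, train)   # 3x1
        if self.fusion_rule == "literal_product":
            left, right = a * c, b * c
        else:
            left, right = a + c, b + c
        fused = left * right
        self._cache = (a, b, c, left, right) if train else None
        return self.dropout.forward(fused, train)

    def backward(self, g):
        g = self.dropout.backward(g)
        a, b, c, left, right = self._cache
        gl = g * right
        gr = g * left
        if self.fusion_rule == "literal_product":
            ga, gb = gl * c, gr * c
            gc = gl * a + gr * b
        else:
            ga, gb = gl, gr
            gc = gl + gr
        return (self.path_horizontal.backward(ga)
                + self.path_vertical.backward(gb)
                + self.path_square.backward(gc))


class Decoder(Module):
    """Calibrating decoder producing the single-channel probability map."""

    def __init__(self, encoder_channels: int, bridge_channels: int, rng=None,
                 dtype=np.float32):
        super().__init__()
        self.compress = Conv2d(encoder_channels, bridge_channels, (1, 1),
                               rng=rng, dtype=dtype)
        self.compress_bn = BatchNorm2d(bridge_channels, dtype=dtype)
        self.compress_act = ReLU()
        self.out_conv = Conv2d(3 * bridge_channels, 1, (1, 1), rng=rng, dtype=dtype)
        self.out_bn = BatchNorm2d(1, dtype=dtype)
        self.out_act = Sigmoid()
        self.bridge_channels = bridge_channels
        self._cache = None

    def forward(self, encoded, bridge, train=False):
        if encoded.shape[1:3] != bridge.shape[1:3]:
            raise ShapeError(
                f"encoder map {encoded.shape} and bridge map {bridge.shape} "
                "disagree on spatial dimensions")
        compressed = self.compress_act.forward(
            self.compress_bn.forward(self.compress.forward(encoded, train), train),
            train)
        calibrated = compressed * bridge
        fused = np.concatenate([bridge, compressed, calibrated], axis=3)
        pred = self.out_act.forward(
            self.out_bn.forward(self.out_conv.forward(fused, train), train), train)
        self._cache = (bridge, compressed) if train else None
        return DecoderFeatures(bridge=bridge, compressed=compressed,
                               calibrated=calibrated, fused=fused, prediction=pred)

    def backward(self, g_pre_sigmoid_bn, g_compressed_extra=None,
                 g_calibrated_extra=None):
        """Backward pass.

        ``g_pre_sigmoid_bn`` is the gradient at the output-convolution result
        (before BN and sigmoid the caller has already folded those in, or
        after them via their backward).  Extra gradients flowing into the
        compressed / calibrated maps from auxiliary heads may be supplied.
        Returns (grad wrt encoder map, grad wrt bridge map).
        """
        bridge, compressed = self._cache
        g_fused = self.out_conv.backward(self.out_bn.backward(g_pre_sigmoid_bn))
        bc = self.bridge_channels
        g_bridge = g_fused[..., 0:bc].copy()
        g_comp = g_fused[..., bc:2 * bc].copy()
        g_cal = g_fused[..., 2 * bc:3 * bc].copy()
        if g_calibrated_extra is not None:
            g_cal += g_calibrated_extra
        g_comp += g_cal * bridge
        g_bridge += g_cal * compressed
        if g_compressed_extra is not None:
            g_comp += g_compressed_extra
        g_encoded = self.compress.backward(
            self.compress_bn.backward(self.compress_act.backward(g_comp)))
        return g_encoded, g_bridge


class AuxHead(Module):
    """1x1 convolution + sigmoid deep-supervision head."""

    def __init__(self, in_ch: int, rng=None, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(in_ch, 1, (1, 1), rng=rng, dtype=dtype)
        self.act = Sigmoid()

    def forward(self, x, train=False):
        return self.act.forward(self.conv.forward(x, train), train)

    def backward_from_logit_grad(self, g_logit):
        """Backward given the gradient at the pre-sigmoid logit."""
        return self.conv.backward(g_logit)


class MSFANet(Module):
    """The full network: MSF encoder + ASCS bridge + calibrating decoder +
    three auxiliary deep-supervision heads.

    ``forward`` returns a :class:`DecoderFeatures`; in inference mode
    (``train=False``) dropout is off and batch norm uses running statistics,
    so repeated passes are bit-identical.
    """

    IN_CHANNELS = 3

    def __init__(self, config: ModelConfig | None = None, dtype=np.float32):
        super().__init__()
        config = config or ModelConfig()
        self.config = config
        rng = np.random.default_rng(config.seed)
        dropout_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0])
        self.encoder = MSFEncoder(self.IN_CHANNELS, config.branch_channels,
                                  config.rates, config.scse_placement,
                                  config.scse_reduction, rng=rng, dtype=dtype)
        self.bridge = ASCSBridge(self.IN_CHANNELS, config.bridge_channels,
                                 config.fusion_rule, config.dropout_rate,
                                 rng=rng, dropout_rng=dropout_rng, dtype=dtype)
        self.decoder = Decoder(self.encoder.out_channels,
                               config.bridge_channels, rng=rng, dtype=dtype)
        self.head_bridge = AuxHead(config.bridge_channels, rng=rng, dtype=dtype)
        self.head_compressed = AuxHead(config.decoder_compress_channels,
                                       rng=rng, dtype=dtype)
        self.head_calibrated = AuxHead(config.decoder_compress_channels,
                                       rng=rng, dtype=dtype)
        self._features: DecoderFeatures | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> DecoderFeatures:
        if x.ndim != 4 or x.shape[3] != self.IN_CHANNELS:
            raise ShapeError(f"expected N x H x W x 3 input, got shape {x.shape}")
        if not np.isfinite(x).all():
            raise ValueError("input contains non-finite values")
        encoded = self.encoder.forward(x, train)
        bridge = self.bridge.forward(x, train)
        feats = self.decoder.forward(encoded, bridge, train)
        feats.aux = (self.head_bridge.forward(bridge, train),
                     self.head_compressed.forward(feats.compressed, train),
                     self.head_calibrated.forward(feats.calibrated, train))
        self._features = feats if train else None
        return feats

    def backward_from_labels(self, labels: np.ndarray, weights) -> None:
        """Accumulate gradients of the composite deep-supervision loss.

        Every head ends in a sigmoid compared to ``labels`` by mean binary
        cross-entropy, so each head's logit gradient is
        weight * (p - y) / n_pixels; this fused form is exact and avoids the
        p(1-p) cancellation.
        """
        feats = self._features
        if feats is None:
            raise RuntimeError("backward_from_labels requires a training forward")
        y = labels.astype(feats.prediction.dtype)
        if y.shape != feats.prediction.shape:
            raise ShapeError(
                f"labels shape {y.shape} != prediction shape {feats.prediction.shape}")
        mu, nu, xi = weights.as_tuple()
        n = y.size
        # main head: fold sigmoid in analytically -> gradient at BN output
        g_bn_out = (feats.prediction - y) / n
        g_comp_extra = self.head_compressed.backward_from_logit_grad(
            nu * (feats.aux[1] - y) / n)
        g_cal_extra = self.head_calibrated.backward_from_logit_grad(
            xi * (feats.aux[2] - y) / n)
        g_encoded, g_bridge = self.decoder.backward(
            g_bn_out, g_comp_extra, g_cal_extra)
        g_bridge = g_bridge + self.head_bridge.backward_from_logit_grad(
            mu * (feats.aux[0] - y) / n)
        gx = self.encoder.backward(g_encoded)
        gx += self.bridge.backward(g_bridge)
        self._features = None

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode probability map, N x H x W x 1 in (0, 1)."""
        return self.forward(x, train=False).prediction

    def make_optimizer(self, **kwargs) -> Adam:
        return Adam(list(self.parameters()), **kwargs)


def count_parameters(model: Module) -> int:
    """Total trainable scalar parameter count of a module tree."""
    return model.num_parameters()


def parameter_breakdown(model: Module) -> dict[str, int]:
    """Per-top-level-block trainable parameter counts (plus ``total``)."""
    out = {}
    for name, sub in model._modules.items():
        out[name] = sub.num_parameters()
    out["total"] = model.num_parameters()
    return out


def build_model(config: ModelConfig | None = None, dtype=np.float32) -> MSFANet:
    return MSFANet(config or ModelConfig(), dtype=dtype)


def multiply_accumulates(model: Module, spatial: tuple[int, int] = (224, 224)) -> int:
    """Static forward multiply-accumulate estimate at a given resolution.

    Every block preserves spatial size, so each convolution contributes
    H * W * kh * kw * C_in * C_out and each dense layer its weight count.
    """
    h, w = spatial
    total = 0

    def visit(m: Module):
        nonlocal total
        if isinstance(m, Conv2d):
            total += h * w * m.kh * m.kw * m.in_channels * m.out_channels
        elif isinstance(m, Dense):
            total += m.weight.data.size
        for sub in m._modules.values():
            visit(sub)

    visit(model)
    return total
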