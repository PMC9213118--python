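"""Minimal NumPy neural-network layer library.

Implements exactly the primitives the segmentation network needs — 2-D
convolution with dilation and "same" padding, batch normalization, ReLU,
sigmoid, inverted dropout, dense layers — each with a hand-written backward
pass, plus an Adam optimizer.  Layout is NHWC throughout; parameters default
to float32 (float64 is supported for finite-difference gradient checking).

The API intentionally mirrors the familiar ``Module`` idiom: composite blocks
register sub-modules and parameters by attribute assignment, and
``named_state`` / ``load_state`` give flat, order-stable checkpoints.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Dense",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "Adam",
    "kaiming_normal",
    "relu",
    "sigmoid",
]


class ConfigError(ValueError):
    """Invalid layer or model configuration."""


class ShapeError(ValueError):
    """Input shape incompatible with the layer."""


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic, clamped to the open interval (0, 1).

    The clamp (1e-7 each side) keeps saturated float32 gates and probability
    maps strictly inside (0, 1), as the prediction contract requires.
    """
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return np.clip(out, 1e-7, 1.0 - 1e-7)


def kaiming_normal(rng: np.random.Generator, shape: tuple, fan_in: int,
                   dtype=np.float32) -> np.ndarray:
    """He initialization (fan-in mode) for ReLU networks."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class with automatic sub-module / parameter registration."""

    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, Param):
            self._params[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        if name not in self._buffers:
            raise KeyError(name)
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # ---- traversal -------------------------------------------------
    def parameters(self) -> Iterator[Param]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Param]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Parameters plus persistent buffers (running BN statistics)."""
        out: dict[str, np.ndarray] = {}
        for k, p in self._params.items():
            out[prefix + k] = p.data
        for k, b in self._buffers.items():
            out[prefix + k] = b
        for name, m in self._modules.items():
            out.update(m.named_state(prefix + name + "."))
        return out

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, p in self._params.items():
            src = state[prefix + k]
            if src.shape != p.data.shape:
                raise ShapeError(
                    f"checkpoint array {prefix + k} has shape {src.shape}, "
                    f"expected {p.data.shape}")
            p.data = src.astype(p.data.dtype, copy=True)
            p.grad = np.zeros_like(p.data)
        for k in list(self._buffers):
            src = state[prefix + k]
            self._set_buffer(k, src.astype(self._buffers[k].dtype, copy=True))
        for name, m in self._modules.items():
            m.load_state(state, prefix + name + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


class Conv2d(Module):
    """2-D convolution, NHWC, odd kernels, dilation, "same" padding.

    Implemented as im2col + GEMM.  ``dilation`` d spaces the kernel taps d-1
    pixels apart; "same" padding is d*(k-1)/2 per side so spatial dimensions
    are always preserved.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int] = (3, 3), dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        kh, kw = kernel
        if dilation < 1:
            raise ConfigError(f"dilation must be >= 1, got {dilation}")
        if kh % 2 == 0 or kw % 2 == 0:
            raise ConfigError("only odd kernel extents are supported")
        if in_channels < 1 or out_channels < 1:
            raise ConfigError("channel counts must be positive")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kh, self.kw = kh, kw
        self.dilation = dilation
        fan_in = in_channels * kh * kw
        self.weight = Param(kaiming_normal(rng, (kh, kw, in_channels, out_channels),
                                           fan_in, dtype))
        self.has_bias = bias
        if bias:
            self.bias = Param(np.zeros(out_channels, dtype=dtype))
        self._cache = None

    def _pad_amount(self) -> tuple[int, int]:
        return (self.dilation * (self.kh - 1) // 2,
                self.dilation * (self.kw - 1) // 2)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        ph, pw = self._pad_amount()
        d = self.dilation
        if ph or pw:
            xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        else:
            xp = x
        if self.kh == 1 and self.kw == 1:
            return xp.reshape(n, h, w, c)
        cols = np.empty((n, h, w, self.kh * self.kw * c), dtype=x.dtype)
        t = 0
        for i in range(self.kh):
            for j in range(self.kw):
                cols[..., t * c:(t + 1) * c] = xp[:, i * d:i * d + h,
                                                  j * d:j * d + w, :]
                t += 1
        return cols

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != self.in_channels:
            raise ShapeError(
                f"expected NHWC input with {self.in_channels} channels, "
                f"got shape {x.shape}")
        n, h, w, _ = x.shape
        cols = self._im2col(x)
        k = self.kh * self.kw * self.in_channels
        wmat = self.weight.data.reshape(k, self.out_channels)
        y = cols.reshape(-1, k) @ wmat
        if self.has_bias:
            y += self.bias.data
        self._cache = (cols, x.shape) if train else None
        return y.reshape(n, h, w, self.out_channels)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a training forward")
        cols, xshape = self._cache
        n, h, w, c = xshape
        k = self.kh * self.kw * c
        gmat = g.reshape(-1, self.out_channels)
        self.weight.grad += (cols.reshape(-1, k).T @ gmat).reshape(
            self.weight.data.shape)
        if self.has_bias:
            self.bias.grad += gmat.sum(axis=0)
        wmat = self.weight.data.reshape(k, self.out_channels)
        gcols = (gmat @ wmat.T).reshape(n, h, w, k)
        ph, pw = self._pad_amount()
        d = self.dilation
        if self.kh == 1 and self.kw == 1:
            return gcols
        gxp = np.zeros((n, h + 2 * ph, w + 2 * pw, c), dtype=g.dtype)
        t = 0
        for i in range(self.kh):
            for j in range(self.kw):
                gxp[:, i * d:i * d + h, j * d:j * d + w, :] += \
                    gcols[..., t * c:(t + 1) * c]
                t += 1
        return gxp[:, ph:ph + h, pw:pw + w, :]


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.register_buffer("running_mean", np.zeros(channels, dtype=dtype))
        self.register_buffer("running_var", np.ones(channels, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.channels:
            raise ShapeError(f"expected {self.channels} channels, got {x.shape}")
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self._set_buffer("running_mean",
                             ((1 - self.momentum) * self.running_mean
                              + self.momentum * mean).astype(x.dtype))
            self._set_buffer("running_var",
                             ((1 - self.momentum) * self.running_var
                              + self.momentum * var).astype(x.dtype))
        else:
            mean = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if train:
            self._cache = (xhat, invstd)
        else:
            self._cache = None
        return self.gamma.data * xhat + self.beta.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a training forward")
        xhat, invstd = self._cache
        n = g.shape[0] * g.shape[1] * g.shape[2]
        self.gamma.grad += (g * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += g.sum(axis=(0, 1, 2))
        dxhat = g * self.gamma.data
        sum_dxhat = dxhat.sum(axis=(0, 1, 2))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (invstd / n) * (n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class Dense(Module):
    """Fully connected layer on (N, F) inputs — used by the channel gate."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Param(kaiming_normal(rng, (in_features, out_features),
                                           in_features, dtype))
        self.bias = Param(np.zeros(out_features, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._cache = x if train else None
        return x @ self.weight.data + self.bias.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += x.T @ g
        self.bias.grad += g.sum(axis=0)
        return g @ self.weight.data.T


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        self._mask = (x > 0) if train else None
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._out = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = sigmoid(x)
        self._out = out if train else None
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._out * (1 - self._out)


class Dropout(Module):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0 <= rate < 1:
            raise ConfigError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask
        return x * mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        return g * self._mask


class Adam:
    """Adam with external (scheduler-driven) learning rate."""

    def __init__(self, params: list[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
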