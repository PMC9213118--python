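"""Binary cross-entropy and the weighted deep-supervision composite loss."""

from __future__ import annotations

import numpy as np

from .config import LossWeights
from .nn import ShapeError

_EPS = 1e-7


def binary_cross_entropy(pred: np.ndarray, label: np.ndarray) -> float:
    """Mean pixel-wise two-class cross-entropy.

    ``pred`` holds probabilities in (0, 1); probabilities are clamped to
    [1e-7, 1 - 1e-7] before taking logs for numeric safety.
    """
    if pred.shape != label.shape:
        raise ShapeError(f"pred shape {pred.shape} != label shape {label.shape}")
    p = np.clip(np.asarray(pred, dtype=np.float64), _EPS, 1.0 - _EPS)
    y = np.asarray(label, dtype=np.float64)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def composite_loss(features, label: np.ndarray,
                   weights: LossWeights | None = None) -> float:
    """Main-head loss plus mu/nu/xi-weighted auxiliary-head losses.

    ``features`` is a :class:`msfanet.blocks.DecoderFeatures` whose ``aux``
    triple holds the bridge / compressed / calibrated head probability maps.
    """
    weights = weights or LossWeights()
    if features.aux is None:
        raise ValueError("features.aux missing: run the model forward first")
    mu, nu, xi = weights.as_tuple()
    total = binary_cross_entropy(features.prediction, label)
    total += mu * binary_cross_entropy(features.aux[0], label)
    total += nu * binary_cross_entropy(features.aux[1], label)
    total += xi * binary_cross_entropy(features.aux[2], label)
    return total
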