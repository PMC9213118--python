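"""Architecture and loss-weighting configuration.

``ModelConfig`` pins every architectural hyperparameter of the network: the
five dilation rates of the multiscale-fusion (MSF) encoder, the per-branch
channel width G, the channel width of the asymmetric skip-connection bridge,
where the scSE attention gates sit, and how the bridge's three convolution
paths are fused.  ``LossWeights`` carries the deep-supervision coefficients
(mu, nu, xi), constrained to the unit simplex.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .nn import ConfigError

SCSE_PLACEMENTS = ("none", "I", "II", "I_and_II")
FUSION_RULES = ("literal_product", "sum_product")


@dataclass
class ModelConfig:
    """All architecture hyperparameters of the segmentation network.

    Parameters
    ----------
    rates : dilation rates of the five parallel encoder branches; the first
        must be 1 (a plain 1x1 convolution branch) and the list must be
        strictly increasing.  Default (1, 3, 6, 12, 18).
    branch_channels : channel width G of each encoder branch (default 128).
    kernel_set : admissible kernel extents; fixed at {1, 3}.
    bridge_channels : channel width of the asymmetric bridge (default 3).
    scse_placement : where scSE attention is applied — "I" on each branch
        before fusion, "II" on the concatenated encoder map, "I_and_II" both,
        or "none".
    fusion_rule : how the bridge's 1x3 / 3x1 / 3x3 paths are combined —
        "literal_product" multiplies all pairwise products element-wise,
        "sum_product" multiplies the two (asymmetric + square) sums.
    dropout_rate : dropout applied to the fused bridge map during training.
    scse_reduction : bottleneck reduction ratio of the channel gate.
    decoder_compress_channels : channels of the compressed encoder map; must
        equal ``bridge_channels`` so the pixel-wise calibration product is
        shape-valid.
    seed : seed for weight initialization and dropout.
    """

    rates: tuple[int, ...] = (1, 3, 6, 12, 18)
    branch_channels: int = 128
    kernel_set: tuple[int, ...] = (1, 3)
    bridge_channels: int = 3
    scse_placement: str = "II"
    fusion_rule: str = "literal_product"
    dropout_rate: float = 0.1
    scse_reduction: int = 2
    decoder_compress_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        self.rates = tuple(int(r) for r in self.rates)
        if len(self.rates) != 5:
            raise ConfigError(f"exactly 5 dilation rates required, got {len(self.rates)}")
        if self.rates[0] != 1:
            raise ConfigError("the first branch rate must be 1 (1x1 convolution branch)")
        if any(r < 1 for r in self.rates):
            raise ConfigError("dilation rates must be >= 1")
        if any(b >= a for b, a in zip(self.rates, self.rates[1:])):
            raise ConfigError("dilation rates must be strictly increasing")
        if tuple(sorted(self.kernel_set)) != (1, 3):
            raise ConfigError("kernel_set is fixed at {1, 3}")
        if self.branch_channels < 1:
            raise ConfigError("branch_channels must be >= 1")
        if self.bridge_channels < 1:
            raise ConfigError("bridge_channels must be >= 1")
        if self.scse_placement not in SCSE_PLACEMENTS:
            raise ConfigError(
                f"scse_placement must be one of {SCSE_PLACEMENTS}, "
                f"got {self.scse_placement!r}")
        if self.fusion_rule not in FUSION_RULES:
            raise ConfigError(
                f"fusion_rule must be one of {FUSION_RULES}, got {self.fusion_rule!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.scse_reduction < 1:
            raise ConfigError("scse_reduction must be >= 1")
        if self.decoder_compress_channels != self.bridge_channels:
            raise ConfigError(
                "decoder_compress_channels must equal bridge_channels so the "
                "pixel-wise calibration product is shape-valid")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rates"] = list(self.rates)
        d["kernel_set"] = list(self.kernel_set)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown ModelConfig keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class LossWeights:
    """Deep-supervision loss coefficients (mu, nu, xi) on the unit simplex.

    mu weighs the bridge (Y-hat) head, nu the compressed (Y-tilde-prime)
    head, xi the calibrated (Y-tilde-double-prime) head.  They must each lie
    in [0, 1] and sum to one; the main prediction head always has weight 1.
    """

    mu: float = 1.0 / 3.0
    nu: float = 1.0 / 3.0
    xi: float = 1.0 / 3.0

    def __post_init__(self):
        for name in ("mu", "nu", "xi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"loss coefficient {name}={v} outside [0, 1]")
        total = self.mu + self.nu + self.xi
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"loss coefficients must sum to 1, got mu+nu+xi={total!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mu, self.nu, self.xi)
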