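"""Checkpoint serialization.

A checkpoint is an ``.npz`` of every parameter and running-statistics buffer
plus a JSON sidecar carrying the full architecture configuration and the
preprocessing contract (working resolution, normalization statistics,
binarization threshold), so a checkpoint is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .blocks import MSFANet
from .config import ModelConfig

__all__ = ["save_checkpoint", "load_checkpoint", "sidecar_path"]


def sidecar_path(checkpoint: str | Path) -> Path:
    return Path(checkpoint).with_suffix(".json")


def save_checkpoint(model: MSFANet, path: str | Path,
                    preprocess: dict | None = None,
                    threshold: float = 0.5) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.named_state())
    meta = {"model": model.config.to_dict(),
            "preprocess": preprocess or {},
            "threshold": threshold}
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def load_checkpoint(path: str | Path) -> tuple[MSFANet, dict]:
    """Rebuild the model from a checkpoint; returns (model, sidecar dict)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint {path} does not exist")
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"checkpoint sidecar {side} does not exist")
    meta = json.loads(side.read_text())
    model = MSFANet(ModelConfig.from_dict(meta["model"]))
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    model.load_state(state)
    return model, meta
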