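"""Training and evaluation loops.

Adam drives the weights; the LRAA schedule drives Adam's learning rate from
the per-epoch training loss.  Each epoch logs train loss, validation loss,
validation Dice/IoU and the learning rate; the best model (by validation
Dice) is retained.  Everything is seeded, so two runs with the same seed
produce identical histories.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import MSFANet
from .config import LossWeights
from .losses import composite_loss
from .metrics import evaluate_arrays
from .schedule import LRAAState, lraa_step

__all__ = ["TrainConfig", "train_model", "evaluate_model", "predict_masks"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the headline training recipe: Adam at eta = 1e-4 for
    s = 150 epochs with LRAA annealing from epoch tau = s // 2, batch size 8.
    ``early_stop_dice`` stops training once validation Dice reaches the given
    level (useful for scaled-down runs).
    """

    lr: float = 1e-4
    epochs: int = 150
    batch_size: int = 8
    seed: int = 0
    lr_floor: float = 1e-6
    loss_weights: LossWeights = field(default_factory=LossWeights)
    threshold: float = 0.5
    early_stop_dice: float | None = None


def _as_label(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim == 3:
        y = y[..., None]
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    return y.astype(np.uint8)


def predict_masks(model: MSFANet, x: np.ndarray, threshold: float = 0.5,
                  batch_size: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Inference over a stack of images; returns (probabilities, masks)."""
    probs = []
    for i in range(0, len(x), batch_size):
        probs.append(model.predict_proba(x[i:i + batch_size]))
    proba = np.concatenate(probs, axis=0)
    return proba, (proba >= threshold).astype(np.uint8)


def evaluate_model(model: MSFANet, x: np.ndarray, y: np.ndarray,
                   threshold: float = 0.5, average: str = "micro",
                   batch_size: int = 8) -> dict:
    """Pooled (micro) or per-image-averaged (macro) Dice/IoU on a dataset."""
    if len(x) == 0:
        raise ValueError("empty dataset")
    y = _as_label(y)
    proba, masks = predict_masks(model, x, threshold, batch_size)
    out = evaluate_arrays(masks[..., 0], y[..., 0], average=average)
    out["loss"] = float(np.mean(
        -(y * np.log(np.clip(proba, 1e-7, None))
          + (1 - y) * np.log(np.clip(1 - proba, 1e-7, None)))))
    return out


def train_model(model: MSFANet, train_data: tuple[np.ndarray, np.ndarray],
                val_data: tuple[np.ndarray, np.ndarray],
                config: TrainConfig | None = None,
                ) -> tuple[pd.DataFrame, dict]:
    """Train ``model`` in place; return (history, best state dict).

    ``train_data`` / ``val_data`` are (images NHWC float32, masks NHW[1]
    binary) tuples.  History columns: epoch, lr, train_loss, val_loss,
    val_dice, val_iou.  The returned state dict is the best-validation-Dice
    snapshot (also restored into the model before returning).
    """
    config = config or TrainConfig()
    x_train, y_train = train_data
    x_val, y_val = val_data
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty dataset")
    y_train = _as_label(y_train)
    y_val = _as_label(y_val)

    rng = np.random.default_rng(config.seed)
    opt = model.make_optimizer()
    state = LRAAState(lr=config.lr, total_epochs=config.epochs,
                      lr_floor=config.lr_floor)
    best_dice = -1.0
    best_state: dict | None = None
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_train))
        total, seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = x_train[idx]
            yb = y_train[idx].astype(np.float32)
            model.zero_grad()
            feats = model.forward(xb, train=True)
            loss = composite_loss(feats, yb, config.loss_weights)
            model.backward_from_labels(yb, config.loss_weights)
            opt.step(state.lr)
            total += loss * len(idx)
            seen += len(idx)
        train_loss = total / seen
        val = evaluate_model(model, x_val, y_val, config.threshold)
        rows.append({"epoch": epoch, "lr": state.lr,
                     "train_loss": train_loss, "val_loss": val["loss"],
                     "val_dice": val["micro_dice"], "val_iou": val["micro_iou"]})
        if val["micro_dice"] > best_dice:
            best_dice = val["micro_dice"]
            best_state = copy.deepcopy(model.named_state())
        state = lraa_step(state, train_loss)
        if (config.early_stop_dice is not None
                and val["micro_dice"] >= config.early_stop_dice):
            break
    history = pd.DataFrame(rows)
    if best_state is not None:
        model.load_state(best_state)
    return history, best_state
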