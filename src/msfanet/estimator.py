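"""Scikit-learn style estimator facade over the segmentation network.

``MSFASegmenter`` behaves like an sklearn classifier whose samples are RGB
images and whose targets are binary masks: construct with hyperparameters,
``fit(X, y)``, then ``predict`` masks or ``predict_proba`` probability maps.
``get_params`` / ``set_params`` / ``clone`` work as usual, so the estimator
composes with sklearn model-selection utilities that accept 4-D inputs.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .blocks import MSFANet, count_parameters
from .config import LossWeights, ModelConfig
from .train import TrainConfig, evaluate_model, predict_masks, train_model

__all__ = ["MSFASegmenter"]


class MSFASegmenter(BaseEstimator):
    """Dermoscopy lesion segmenter.

    Parameters mirror :class:`msfanet.config.ModelConfig` (architecture) and
    :class:`msfanet.train.TrainConfig` (optimization).  ``X`` is an
    (n_samples, H, W, 3) float array of channel-standardized images; ``y`` is
    (n_samples, H, W) or (n_samples, H, W, 1) binary masks.

    Attributes (after ``fit``)
    --------------------------
    model_ : the trained network
    history_ : per-epoch training log (DataFrame)
    n_parameters_ : trainable parameter count
    best_val_dice_ : best validation Dice reached during training
    """

    def __init__(self, rates=(1, 3, 6, 12, 18), branch_channels=128,
                 bridge_channels=3, scse_placement="II",
                 fusion_rule="literal_product", dropout_rate=0.1,
                 scse_reduction=2, lr=1e-4, epochs=150, batch_size=8,
                 lr_floor=1e-6, mu=1 / 3, nu=1 / 3, xi=1 / 3, threshold=0.5,
                 val_fraction=0.125, early_stop_dice=None, seed=0):
        self.rates = rates
        self.branch_channels = branch_channels
        self.bridge_channels = bridge_channels
        self.scse_placement = scse_placement
        self.fusion_rule = fusion_rule
        self.dropout_rate = dropout_rate
        self.scse_reduction = scse_reduction
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_floor = lr_floor
        self.mu = mu
        self.nu = nu
        self.xi = xi
        self.threshold = threshold
        self.val_fraction = val_fraction
        self.early_stop_dice = early_stop_dice
        self.seed = seed

    # ---- config assembly ------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(rates=tuple(self.rates),
                           branch_channels=self.branch_channels,
                           bridge_channels=self.bridge_channels,
                           scse_placement=self.scse_placement,
                           fusion_rule=self.fusion_rule,
                           dropout_rate=self.dropout_rate,
                           scse_reduction=self.scse_reduction,
                           decoder_compress_channels=self.bridge_channels,
                           seed=self.seed)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, epochs=self.epochs,
                           batch_size=self.batch_size, seed=self.seed,
                           lr_floor=self.lr_floor,
                           loss_weights=LossWeights(self.mu, self.nu, self.xi),
                           threshold=self.threshold,
                           early_stop_dice=self.early_stop_dice)

    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(
                f"X must be (n_samples, H, W, 3), got shape {X.shape}")
        return X

    # ---- sklearn API ----------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train the network; a validation split is carved from (X, y) when
        no explicit validation set is supplied."""
        X = self._check_X(X)
        y = np.asarray(y)
        if X_val is None:
            n_val = max(int(round(self.val_fraction * len(X))), 1)
            if n_val >= len(X):
                raise ValueError("not enough samples to carve a validation split")
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(X))
            val_idx, train_idx = order[:n_val], order[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[train_idx], y[train_idx]
        else:
            X_val = self._check_X(X_val)
            y_val = np.asarray(y_val)
        self.model_ = MSFANet(self._model_config())
        self.n_parameters_ = count_parameters(self.model_)
        self.history_, _ = train_model(self.model_, (X, y), (X_val, y_val),
                                       self._train_config())
        self.best_val_dice_ = float(self.history_["val_dice"].max())
        return self

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this MSFASegmenter instance is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel lesion probability maps, (n_samples, H, W)."""
        self._require_fitted()
        proba, _ = predict_masks(self.model_, self._check_X(X),
                                 self.threshold, self.batch_size)
        return proba[..., 0]

    def predict(self, X) -> np.ndarray:
        """Binary lesion masks, (n_samples, H, W) uint8."""
        self._require_fitted()
        _, masks = predict_masks(self.model_, self._check_X(X),
                                 self.threshold, self.batch_size)
        return masks[..., 0]

    def score(self, X, y) -> float:
        """Micro-averaged Dice coefficient on (X, y)."""
        self._require_fitted()
        res = evaluate_model(self.model_, self._check_X(X), np.asarray(y),
                             self.threshold, average="micro",
                             batch_size=self.batch_size)
        return res["micro_dice"]
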