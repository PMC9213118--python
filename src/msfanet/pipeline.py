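"""Run configuration and the command implementations behind the CLI.

A run is described by one YAML file (see :class:`RunConfig`): architecture
hyperparameters, loss coefficients, optimization settings, the data source
(an ISIC-style directory or a synthetic-dataset recipe) and an output
directory.  Unknown keys anywhere in the file are errors.  Every run writes
its resolved configuration next to its outputs, so results are traceable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .blocks import MSFANet, multiply_accumulates, parameter_breakdown
from .config import LossWeights, ModelConfig
from .data import (DEFAULT_FRACTIONS, IMAGENET_MEAN, IMAGENET_STD,
                   compute_normalization, load_isic_dataset, load_pairs,
                   preprocess)
from .io import load_checkpoint, save_checkpoint
from .nn import ConfigError
from .synth import generate_dataset
from .train import TrainConfig, evaluate_model, train_model

__all__ = ["RunConfig", "run_train", "run_eval", "run_predict", "run_ablate",
           "run_summary"]

log = logging.getLogger("msfanet")


def _check_keys(d: dict, allowed: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown {context} keys: {sorted(unknown)}")


@dataclass
class SyntheticDataConfig:
    n: int = 60
    image_size: tuple[int, int] = (64, 64)
    category_mix: dict[str, float] = field(
        default_factory=lambda: {"small": 1.0, "prominent": 1.0,
                                 "irregular_edge": 1.0})
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticDataConfig":
        _check_keys(d, {"n", "image_size", "category_mix", "seed"},
                    "data.synthetic")
        if "image_size" in d:
            d = dict(d, image_size=tuple(d["image_size"]))
        return cls(**d)


@dataclass
class DataConfig:
    root: str | None = None
    synthetic: SyntheticDataConfig | None = None
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    image_size: int = 224
    normalization: str = "dataset"   # or "imagenet"
    augment: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "DataConfig":
        _check_keys(d, {"root", "synthetic", "fractions", "image_size",
                        "normalization", "augment", "seed"}, "data")
        d = dict(d)
        if "synthetic" in d and d["synthetic"] is not None:
            d["synthetic"] = SyntheticDataConfig.from_dict(d["synthetic"])
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        cfg = cls(**d)
        if cfg.normalization not in ("dataset", "imagenet"):
            raise ConfigError(
                f"data.normalization must be 'dataset' or 'imagenet', "
                f"got {cfg.normalization!r}")
        if cfg.root is None and cfg.synthetic is None:
            raise ConfigError("data: either 'root' or 'synthetic' is required")
        return cfg


@dataclass
class RunConfig:
    """Complete description of one training / ablation run."""

    output_dir: str
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    train: TrainConfig = field(default_factory=TrainConfig)
    data: DataConfig = field(default_factory=DataConfig)
    ablation: dict | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, {"output_dir", "model", "loss", "train", "data",
                        "ablation"}, "run config")
        if "output_dir" not in d:
            raise ConfigError("run config requires 'output_dir'")
        if "data" not in d:
            raise ConfigError("run config requires a 'data' section")
        model = ModelConfig.from_dict(d.get("model", {}) or {})
        loss_d = d.get("loss", {}) or {}
        _check_keys(loss_d, {"mu", "nu", "xi"}, "loss")
        loss = LossWeights(**loss_d) if loss_d else LossWeights()
        train_d = dict(d.get("train", {}) or {})
        _check_keys(train_d, {"lr", "epochs", "batch_size", "seed",
                              "lr_floor", "threshold", "early_stop_dice"},
                    "train")
        train = TrainConfig(loss_weights=loss, **train_d)
        data = DataConfig.from_dict(d["data"] or {})
        ablation = d.get("ablation")
        if ablation is not None:
            _check_keys(ablation, {"rate_sets", "placements"}, "ablation")
            if not ablation.get("rate_sets") or not ablation.get("placements"):
                raise ConfigError(
                    "ablation requires non-empty 'rate_sets' and 'placements'")
        return cls(output_dir=d["output_dir"], model=model, loss=loss,
                   train=train, data=data, ablation=ablation)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(d)

    def resolved_dict(self) -> dict:
        out = {
            "output_dir": self.output_dir,
            "model": self.model.to_dict(),
            "loss": {"mu": self.loss.mu, "nu": self.loss.nu, "xi": self.loss.xi},
            "train": {k: v for k, v in dataclasses.asdict(self.train).items()
                      if k != "loss_weights"},
            "data": dataclasses.asdict(self.data),
        }
        if self.ablation is not None:
            out["ablation"] = self.ablation
        return out


def _setup_logging(output_dir: Path) -> None:
    output_dir.mkdir(parents=True, exist_ok=True)
    log.setLevel(logging.INFO)
    have_file = any(isinstance(h, logging.FileHandler)
                    and Path(h.baseFilename).parent == output_dir
                    for h in log.handlers)
    if not have_file:
        fh = logging.FileHandler(output_dir / "run.log")
        fh.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)


def _prepare_data(cfg: RunConfig, output_dir: Path):
    """Materialize the dataset and return model-ready split arrays."""
    data = cfg.data
    if data.root is not None:
        root = Path(data.root)
        if not root.exists():
            raise FileNotFoundError(f"data root {root} does not exist")
    else:
        root = output_dir / "data"
        if not (root / "manifest.csv").exists():
            log.info("generating %d synthetic pairs under %s",
                     data.synthetic.n, root)
            generate_dataset(root, data.synthetic.n,
                             data.synthetic.category_mix,
                             data.synthetic.image_size, data.synthetic.seed)
    split = load_isic_dataset(root, data.fractions, data.seed)
    if data.normalization == "dataset":
        mean, std = compute_normalization(p for p, _ in split.train)
    else:
        mean, std = IMAGENET_MEAN, IMAGENET_STD
    size = data.image_size
    aug_seed = data.seed if data.augment else None
    arrays = {
        "train": load_pairs(split.train, size, mean, std, augment_seed=aug_seed),
        "val": load_pairs(split.val, size, mean, std),
        "test": load_pairs(split.test, size, mean, std),
    }
    meta = {"size": size, "mean": list(map(float, mean)),
            "std": list(map(float, std))}
    return arrays, meta, split


def run_train(cfg: RunConfig) -> dict:
    """Full training run: data, model, LRAA-scheduled Adam, artifacts.

    Writes resolved_config.yaml, history.csv, checkpoint.npz (+ .json
    sidecar) and run.log under ``cfg.output_dir``.
    """
    output_dir = Path(cfg.output_dir)
    _setup_logging(output_dir)
    (output_dir / "resolved_config.yaml").write_text(
        yaml.safe_dump(cfg.resolved_dict(), sort_keys=True))
    arrays, pre_meta, _split = _prepare_data(cfg, output_dir)
    model = MSFANet(cfg.model)
    log.info("model has %d trainable parameters", model.num_parameters())
    history, _ = train_model(model, arrays["train"], arrays["val"], cfg.train)
    for row in history.itertuples(index=False):
        log.info("epoch %d lr %.3g train_loss %.4f val_loss %.4f "
                 "val_dice %.4f val_iou %.4f", row.epoch, row.lr,
                 row.train_loss, row.val_loss, row.val_dice, row.val_iou)
    history.to_csv(output_dir / "history.csv", index=False)
    ckpt = save_checkpoint(model, output_dir / "checkpoint.npz",
                           preprocess=pre_meta, threshold=cfg.train.threshold)
    test_metrics = evaluate_model(model, *arrays["test"], cfg.train.threshold)
    report = {"val_dice": float(history["val_dice"].max()),
              "test_dice": test_metrics["micro_dice"],
              "test_iou": test_metrics["micro_iou"],
              "n_parameters": model.num_parameters(),
              "epochs_run": int(len(history))}
    (output_dir / "report.json").write_text(json.dumps(report, indent=2))
    log.info("test micro Dice %.4f IoU %.4f", report["test_dice"],
             report["test_iou"])
    return {"history": history, "checkpoint": ckpt, "report": report,
            "model": model}


def run_eval(checkpoint: str | Path, data_root: str | Path,
             out_dir: str | Path, threshold: float | None = None) -> dict:
    """Evaluate a checkpoint on every pair under an ISIC-style directory.

    Writes micro- and macro-averaged Dice/IoU as both JSON and CSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, meta = load_checkpoint(checkpoint)
    pre = meta.get("preprocess", {})
    size = pre.get("size", 224)
    mean, std = pre.get("mean"), pre.get("std")
    thr = meta.get("threshold", 0.5) if threshold is None else threshold
    split = load_isic_dataset(data_root, seed=0)
    pairs = split.train + split.val + split.test
    x, y = load_pairs(pairs, size, mean, std)
    res = evaluate_model(model, x, y, thr)
    table = {"micro_dice": res["micro_dice"], "micro_iou": res["micro_iou"],
             "macro_dice": res["macro_dice"], "macro_iou": res["macro_iou"],
             "n_images": len(pairs), "threshold": thr}
    (out_dir / "metrics.json").write_text(json.dumps(table, indent=2))
    pd.DataFrame([table]).to_csv(out_dir / "metrics.csv", index=False)
    return table


def run_predict(checkpoint: str | Path, image_path: str | Path,
                out_path: str | Path, proba_path: str | Path | None = None,
                threshold: float | None = None) -> Path:
    """Segment one image; write the binary mask PNG (0/255 values) and
    optionally the probability map as a 16-bit PNG."""
    model, meta = load_checkpoint(checkpoint)
    pre = meta.get("preprocess", {})
    size = pre.get("size", 224)
    tensor = preprocess(image_path, size=size, mean=pre.get("mean"),
                        std=pre.get("std"))
    thr = meta.get("threshold", 0.5) if threshold is None else threshold
    proba = model.predict_proba(tensor[None])[0, ..., 0]
    mask = (proba >= thr).astype(np.uint8) * 255
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask).save(out_path)
    if proba_path is not None:
        q = np.round(proba * 65535).astype(np.uint16)
        Image.fromarray(q).save(proba_path)
    return out_path


def run_ablate(cfg: RunConfig) -> pd.DataFrame:
    """Rate-set x scSE-placement ablation grid on the configured data.

    Each combination is trained and evaluated on the same splits; the grid
    reports test Dice, IoU and the parameter count per variant.
    """
    if cfg.ablation is None:
        raise ConfigError("config has no 'ablation' section")
    output_dir = Path(cfg.output_dir)
    _setup_logging(output_dir)
    arrays, _pre, _split = _prepare_data(cfg, output_dir)
    rows = []
    for rates in cfg.ablation["rate_sets"]:
        for placement in cfg.ablation["placements"]:
            mc = dataclasses.replace(cfg.model, rates=tuple(rates),
                                     scse_placement=placement)
            model = MSFANet(mc)
            history, _ = train_model(model, arrays["train"], arrays["val"],
                                     cfg.train)
            res = evaluate_model(model, *arrays["test"], cfg.train.threshold)
            rows.append({"rates": "-".join(map(str, rates)),
                         "scse": placement,
                         "dice": res["micro_dice"], "iou": res["micro_iou"],
                         "params": model.num_parameters(),
                         "epochs_run": len(history)})
            log.info("ablation rates=%s scse=%s dice=%.4f iou=%.4f params=%d",
                     rates, placement, res["micro_dice"], res["micro_iou"],
                     model.num_parameters())
    grid = pd.DataFrame(rows)
    output_dir.mkdir(parents=True, exist_ok=True)
    grid.to_csv(output_dir / "ablation.csv", index=False)
    return grid


def run_summary(cfg: ModelConfig | RunConfig | None = None,
                image_size: int = 224) -> dict:
    """Parameter and multiply-accumulate summary of a model configuration."""
    if isinstance(cfg, RunConfig):
        mc = cfg.model
    else:
        mc = cfg or ModelConfig()
    model = MSFANet(mc)
    breakdown = parameter_breakdown(model)
    return {"blocks": {k: v for k, v in breakdown.items() if k != "total"},
            "total_parameters": breakdown["total"],
            "multiply_accumulates": multiply_accumulates(
                model, (image_size, image_size)),
            "image_size": image_size}
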