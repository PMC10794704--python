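"""Experiment configuration and the end-to-end run driver.

An experiment reads a class-per-directory training tree (and optionally a
held-out testing tree), preprocesses every image through the
brain-extraction chain, trains ``n_folds`` cross-validated models, picks
the checkpoint with the best validation accuracy, evaluates it, and
writes every artifact — config echo, per-fold histories, checkpoints,
metric report, confusion matrix, ROC points — under one run directory.

Config files are YAML (JSON is a YAML subset and also accepted); every
default equals the published protocol value, so an empty override file
reproduces the reference configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .augment import AugmentConfig
from .data import load_arrays, load_image_folder
from .evaluate import evaluate_model
from .explain import ExplainConfig
from .model import ModelConfig, IPPMConfig, build_neuronet19
from .preprocess import PreprocessConfig
from .train import TrainConfig, run_cv

log = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "setup_logging",
           "save_checkpoint", "load_checkpoint"]


def setup_logging(level: int = logging.INFO, logfile: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    data_dir: str = "data/Training"
    test_dir: str | None = None
    out_dir: str = "runs"
    run_name: str | None = None  # default: timestamp
    base_seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    explain: ExplainConfig = field(default_factory=ExplainConfig)

    def validate(self) -> None:
        self.preprocess.validate()
        self.augment.validate()
        self.model.validate()
        self.train.validate()
        self.explain.validate()

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ExperimentConfig":
        d = dict(d or {})

        def sub(cls, key, **fixups):
            raw = dict(d.pop(key, {}) or {})
            for k, fn in fixups.items():
                if k in raw and raw[k] is not None:
                    raw[k] = fn(raw[k])
            return cls(**raw)

        pre = sub(PreprocessConfig, "preprocess")
        aug = sub(AugmentConfig, "augment", compose_order=tuple)
        model_raw = dict(d.pop("model", {}) or {})
        if "ippm" in model_raw and model_raw["ippm"] is not None:
            ippm_raw = dict(model_raw["ippm"])
            if "pool_sizes" in ippm_raw:
                ippm_raw["pool_sizes"] = tuple(ippm_raw["pool_sizes"])
            model_raw["ippm"] = IPPMConfig(**ippm_raw)
        if "head_filters" in model_raw and model_raw["head_filters"] is not None:
            model_raw["head_filters"] = tuple(model_raw["head_filters"])
        mdl = ModelConfig(**model_raw)
        train_raw = dict(d.pop("train", {}) or {})
        if "augment" in train_raw:
            if train_raw["augment"] is not None:
                aug_raw = dict(train_raw["augment"])
                if "compose_order" in aug_raw:
                    aug_raw["compose_order"] = tuple(aug_raw["compose_order"])
                train_raw["augment"] = AugmentConfig(**aug_raw)
        else:
            train_raw["augment"] = aug
        trn = TrainConfig(**train_raw)
        expl = sub(ExplainConfig, "explain")
        cfg = ExperimentConfig(preprocess=pre, augment=aug, model=mdl,
                               train=trn, explain=expl, **d)
        cfg.validate()
        return cfg

    @staticmethod
    def from_yaml(path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return ExperimentConfig.from_dict(yaml.safe_load(fh) or {})


def save_checkpoint(path: str | Path, state: list[np.ndarray]) -> None:
    np.savez(path, **{f"p{i:03d}": v for i, v in enumerate(state)})


def load_checkpoint(path: str | Path) -> list[np.ndarray]:
    with np.load(path) as z:
        return [z[k] for k in sorted(z.files)]


def _history_csv(path: Path, history) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "loss", "accuracy", "val_loss", "val_accuracy"])
        for e, row in enumerate(zip(history.loss, history.accuracy,
                                    history.val_loss, history.val_accuracy)):
            w.writerow([e] + [float(v) for v in row])


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute preprocess -> folds -> train -> evaluate; returns run dir."""
    config.validate()
    run_name = config.run_name or time.strftime("%Y%m%d-%H%M%S")
    run_dir = Path(config.out_dir) / run_name
    run_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(logfile=run_dir / "run.log")

    echo = json.dumps(config.to_dict(), indent=2, sort_keys=True)
    (run_dir / "config.json").write_text(echo)
    digest = hashlib.sha256(echo.encode()).hexdigest()
    meta = {"config_sha256": digest, "started": time.strftime("%FT%T")}

    try:
        stage = "load"
        train_index = load_image_folder(config.data_dir, split="train")
        log.info("indexed %d training images in %d classes (%d skipped)",
                 len(train_index), len(train_index.class_names),
                 train_index.skipped)
        test_index = None
        if config.test_dir is not None:
            test_index = load_image_folder(config.test_dir, split="test")
            train_paths = {str(p) for p in train_index.paths()}
            overlap = train_paths & {str(p) for p in test_index.paths()}
            if overlap:
                raise ValueError(
                    f"{len(overlap)} test images also appear in the training "
                    "tree; splits must be disjoint")

        stage = "preprocess"
        x_train, y_train = load_arrays(train_index, config.preprocess)

        stage = "train"
        results, summary = run_cv(x_train, y_train, config.model, config.train)
        for i, (state, history) in enumerate(results):
            _history_csv(run_dir / f"history_fold{i}.csv", history)
            save_checkpoint(run_dir / f"checkpoint_fold{i}.npz", state)
        best_fold = int(np.argmax(summary["best_val_accuracy"]))
        meta["cv_summary"] = summary
        meta["best_fold"] = best_fold

        stage = "evaluate"
        model = build_neuronet19(config.model,
                                 seed=config.train.base_seed + best_fold)
        model.load_state_dict(results[best_fold][0])
        if test_index is not None:
            x_eval, y_eval = load_arrays(test_index, config.preprocess)
            names = test_index.class_names
        else:  # fall back to the best fold's validation split
            from .train import make_folds
            folds = make_folds(y_train, k=config.train.n_folds,
                               seed=config.train.base_seed)
            _, va = folds[best_fold]
            x_eval, y_eval = x_train[va], y_train[va]
            names = train_index.class_names
        report, cm, roc = evaluate_model(model, x_eval, y_eval, names)
        report.to_json(run_dir / "metrics.json")
        cm.to_csv(run_dir / "confusion_matrix.csv")
        roc.to_csv(run_dir / "roc.csv")
        meta["test_accuracy"] = report.accuracy
        meta["finished"] = time.strftime("%FT%T")
        (run_dir / "meta.json").write_text(json.dumps(meta, indent=2))
    except Exception as exc:
        meta["failed_stage"] = stage
        meta["error"] = repr(exc)
        (run_dir / "meta.json").write_text(json.dumps(meta, indent=2))
        raise RuntimeError(f"experiment failed in stage {stage!r}: {exc}") from exc
    return run_dir
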