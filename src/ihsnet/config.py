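"""Pipeline configuration and the end-to-end runner.

A single YAML document (or nested dict) configures every stage --
phantom simulation, preprocessing, SMOTE balancing, model, loss,
training, evaluation -- under one global seed.  Defaults reproduce the
reference training hyperparameters (input 256, lr 1e-4, drop factor
0.5, 60 epochs, batch 32, Adam).  ``run_pipeline`` executes
simulate -> preprocess -> balance -> train -> evaluate, each stage
feeding the next, with stage timings and seeds logged.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import balance as balance_mod
from . import phantom as phantom_mod
from . import preprocess as preprocess_mod
from . import trainer as trainer_mod
from .dataset import DatasetManifest, split_patientwise
from .metrics import build_report
from .model import MUNet, MUNetConfig
from .phantom import CLASS_NAMES, PhantomSpec

_log = logging.getLogger("ihsnet")

#: Reference per-class slice counts of the working dataset (all slices,
#: train + test) and the matching SMOTE targets / test counts.
ACTUAL_COUNTS = {"IVH": 24, "IPH": 73, "SAH": 18, "SDH": 56, "EDH": 173}
BEFORE_SMOTE_COUNTS = {"IVH": 18, "IPH": 58, "SAH": 14, "SDH": 45, "EDH": 138}
SMOTE_TARGETS = {"IVH": 385, "IPH": 400, "SAH": 403, "SDH": 364, "EDH": 408}
TEST_COUNTS = {"IVH": 6, "IPH": 15, "SAH": 4, "SDH": 11, "EDH": 35}

DEFAULTS: dict = {
    "seed": 0,
    "phantom": {
        "image_size": 256,
        "lesion_scale": 0.02,
        "noise_sd": 4.0,
        "counts": dict(ACTUAL_COUNTS),
        "slices_per_patient": 30,
    },
    "preprocess": {
        "size": 256,
        "clahe_clip": 2.0,
        "clahe_grid": [8, 8],
        "apply_clahe": True,
    },
    "split": {"test_fraction": 0.2},
    "balance": {
        "k_neighbors": 5,
        "targets": dict(SMOTE_TARGETS),
        "enabled": True,
    },
    "model": {
        "base_channels": 64,
        "num_seg_classes": 6,
        "num_cls_classes": 5,
        "leaky_slope": 0.001,
        "upsample_mode": "bilinear",
    },
    "loss": {"lambda": 1.0, "gamma": 2.0, "alpha": 0.25, "smooth": 1.0},
    "train": {
        "learning_rate": 1.0e-4,
        "lr_drop_factor": 0.5,
        "epochs": 60,
        "batch_size": 32,
        "optimizer": "adam",
        "patience": 5,
        "val_fraction": 0.1,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge DEFAULTS <- YAML file <- overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            cfg = _deep_merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            _log.info("stage %s: started", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                _log.error("stage %s: FAILED (%s)", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            _log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run simulate -> preprocess -> balance -> train -> evaluate.

    Returns a dict of artifact paths; every file is written under
    ``out_dir``.  Deterministic given ``config['seed']``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    artifacts: dict[str, str] = {}

    @_stage("simulate")
    def simulate():
        pc = config["phantom"]
        spec = PhantomSpec(
            image_size=pc["image_size"],
            lesion_scale=pc["lesion_scale"],
            noise_sd=pc["noise_sd"],
        )
        manifest = phantom_mod.generate_dataset(
            pc["counts"], out_dir / "raw", spec_defaults=spec, seed=seed,
            slices_per_patient=pc["slices_per_patient"],
        )
        manifest.save(out_dir / "manifest.csv")
        artifacts["manifest"] = str(out_dir / "manifest.csv")
        return manifest

    @_stage("preprocess")
    def preprocess(manifest):
        pp = config["preprocess"]
        clahe = (
            preprocess_mod.ClaheParams(pp["clahe_clip"], tuple(pp["clahe_grid"]))
            if pp["apply_clahe"]
            else None
        )
        manifest = preprocess_mod.preprocess_manifest(
            manifest, out_dir / "preprocessed", target_size=pp["size"], clahe=clahe
        )
        manifest = split_patientwise(
            manifest, test_fraction=config["split"]["test_fraction"], seed=seed
        )
        manifest.save(out_dir / "manifest_preprocessed.csv")
        artifacts["manifest_preprocessed"] = str(out_dir / "manifest_preprocessed.csv")
        return manifest

    @_stage("balance")
    def balance(manifest):
        bc = config["balance"]
        if not bc["enabled"]:
            return manifest
        # only oversample classes already below their targets
        current = manifest.class_counts("train")
        targets = {
            c: t for c, t in bc["targets"].items() if t >= current.get(c, 0)
        }
        cfg = balance_mod.SmoteConfig(
            k_neighbors=bc["k_neighbors"], target_counts=targets, rng_seed=seed
        )
        manifest = balance_mod.balance_training_set(manifest, cfg, out_dir / "smote")
        manifest.save(out_dir / "manifest_balanced.csv")
        artifacts["manifest_balanced"] = str(out_dir / "manifest_balanced.csv")
        return manifest

    @_stage("train")
    def train_stage(manifest):
        mc = config["model"]
        tc = config["train"]
        lc = config["loss"]
        model = MUNet(
            MUNetConfig(
                input_size=config["preprocess"]["size"],
                base_channels=mc["base_channels"],
                num_seg_classes=mc["num_seg_classes"],
                num_cls_classes=mc["num_cls_classes"],
                leaky_slope=mc["leaky_slope"],
                upsample_mode=mc["upsample_mode"],
                seed=seed,
            )
        )
        cfg = trainer_mod.TrainConfig(
            input_size=config["preprocess"]["size"],
            learning_rate=tc["learning_rate"],
            lr_drop_factor=tc["lr_drop_factor"],
            epochs=tc["epochs"],
            batch_size=tc["batch_size"],
            optimizer=tc["optimizer"],
            seed=seed,
            patience=tc["patience"],
            val_fraction=tc["val_fraction"],
            loss_lambda=lc["lambda"],
            focal_gamma=lc["gamma"],
            focal_alpha=lc["alpha"],
            dice_smooth=lc["smooth"],
        )
        if cfg.epochs > 0:
            history = trainer_mod.train(model, manifest, cfg, out_dir / "run")
            hist_path = out_dir / "run" / "history.json"
            hist_path.parent.mkdir(parents=True, exist_ok=True)
            hist_path.write_text(
                json.dumps(
                    {
                        "seed": seed,
                        "train_loss": history.train_loss,
                        "val_loss": history.val_loss,
                        "train_cls_acc": history.train_cls_acc,
                        "val_cls_acc": history.val_cls_acc,
                        "learning_rate": history.learning_rate,
                        "best_epoch": history.best_epoch,
                    },
                    indent=2,
                )
            )
            artifacts["history"] = str(hist_path)
            if history.checkpoint_path:
                artifacts["checkpoint"] = history.checkpoint_path
        return model

    @_stage("evaluate")
    def evaluate(model, manifest):
        raw = trainer_mod.evaluate_model(model, manifest, split="test")
        report = build_report(
            raw["truths"], raw["preds"], raw["scores"],
            raw["dice"], raw["iou"], list(CLASS_NAMES),
        )
        path = out_dir / "metrics_report.json"
        report.to_json(path)
        artifacts["metrics_report"] = str(path)
        return report

    manifest = simulate()
    manifest = preprocess(manifest)
    manifest = balance(manifest)
    model = train_stage(manifest)
    evaluate(model, manifest)
    return artifacts
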