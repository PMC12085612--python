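"""Desk-scale reference experiments.

The full-size configuration (256 x 256 slices, 64 base channels,
60 epochs, batch 32) targets GPU training on clinical data; these
experiments scale the same pipeline down so that a complete train /
evaluate cycle runs in minutes on one CPU core and demonstrates that
every stage works end to end.

The scaled study trains an 8-base-channel network on about 200
synthetic 64 x 64 phantoms (50 per class, 200 in the training split
after a patient-wise 80/20 split) for 10 epochs.  Run settings for this
short budget: Adam at 1e-4 would barely move in ~500 updates, so the
desk run uses learning rate 5e-3 with batch size 4, focal weight
alpha = 1 and plateau patience 3; lesions occupy 8% of the image area
(the "large, well-separated lesions" regime the phantom priors are
designed around).  The reference defaults remain untouched in
``TrainConfig``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .dataset import split_patientwise
from .metrics import ConfusionMatrix
from .model import MUNet, MUNetConfig
from .phantom import CLASS_NAMES, PhantomSpec, generate_dataset
from .preprocess import ClaheParams, preprocess_manifest
from .trainer import PlateauScheduler, TrainConfig, evaluate_model, train

_log = logging.getLogger("ihsnet")

DESK_IMAGE_SIZE = 64
DESK_BASE_CHANNELS = 8
DESK_PER_CLASS = 50
DESK_LESION_SCALE = 0.08
DESK_EPOCHS = 10
DESK_LEARNING_RATE = 5e-3
DESK_BATCH_SIZE = 4


def desk_scale_study(seed: int, work_dir: str | Path) -> dict:
    """Train and evaluate the scaled-down pipeline; returns its results.

    Generates 50 phantoms per class at 64 x 64, splits patient-wise
    80/20, CLAHE-preprocesses everything, trains a base-8 network for
    10 epochs and evaluates on the held-out phantoms.  Returns initial
    and final training loss, held-out mean foreground Dice (per-slice,
    true class), held-out classification accuracy, and the confusion
    matrix.  Deterministic given ``seed``.
    """
    work_dir = Path(work_dir)
    spec = PhantomSpec(
        image_size=DESK_IMAGE_SIZE, lesion_scale=DESK_LESION_SCALE, noise_sd=4.0
    )
    manifest = generate_dataset(
        {name: DESK_PER_CLASS for name in CLASS_NAMES},
        work_dir / "raw",
        spec_defaults=spec,
        seed=seed,
        slices_per_patient=5,
    )
    manifest = preprocess_manifest(
        manifest, work_dir / "pre", target_size=DESK_IMAGE_SIZE,
        clahe=ClaheParams(2.0, (8, 8)),
    )
    manifest = split_patientwise(manifest, test_fraction=0.2, seed=seed)

    model = MUNet(
        MUNetConfig(
            input_size=DESK_IMAGE_SIZE, base_channels=DESK_BASE_CHANNELS, seed=seed
        )
    )
    cfg = TrainConfig(
        input_size=DESK_IMAGE_SIZE,
        learning_rate=DESK_LEARNING_RATE,
        epochs=DESK_EPOCHS,
        batch_size=DESK_BATCH_SIZE,
        seed=seed,
        patience=3,
        focal_alpha=1.0,
    )
    history = train(model, manifest, cfg, out_dir=work_dir / "run")

    raw = evaluate_model(model, manifest, split="test")
    accuracy = float((raw["truths"] == raw["preds"]).mean())
    mean_dice = float(np.mean(list(raw["dice"].values())))
    cm = ConfusionMatrix.from_predictions(raw["truths"], raw["preds"], len(CLASS_NAMES))
    _log.info(
        "desk-scale study (seed %d): loss %.3f -> %.3f, held-out acc %.3f, "
        "mean Dice %.3f", seed, history.train_loss[0], history.train_loss[-1],
        accuracy, mean_dice,
    )
    return {
        "initial_train_loss": history.train_loss[0],
        "final_train_loss": history.train_loss[-1],
        "holdout_accuracy": accuracy,
        "holdout_mean_dice": mean_dice,
        "per_class_dice": raw["dice"],
        "confusion": cm.counts.tolist(),
        "n_train": int(len(manifest.rows("train"))),
        "n_test": int(len(manifest.rows("test"))),
        "history": history,
    }


def plateau_halving_demo(
    initial_lr: float = 1e-4, factor: float = 0.5, patience: int = 1
) -> float:
    """Learning rate after one injected validation plateau.

    Feeds a constant validation loss to the plateau scheduler; with the
    reference settings (lr 1e-4, factor 0.5) the rate halves to 5e-5.
    """
    sched = PlateauScheduler(initial_lr, factor=factor, patience=patience)
    sched.step(1.0)  # first epoch sets the best loss
    for _ in range(patience):
        sched.step(1.0)  # no improvement: plateau
    return sched.lr
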