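"""Training loop: Adam on the multi-task loss, plateau learning-rate
halving, best-model checkpointing, per-epoch curve logging.

Defaults follow the reference hyperparameters: input 256 x 256,
learning rate 1e-4, drop factor 0.5 on a validation-loss plateau,
60 epochs, batch size 32, Adam.  The validation set is 10% of the
training patients (held out patient-wise); the checkpointed "best"
model is the one with the lowest validation loss.  Runs are fully
reproducible given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import CTSlice, DatasetManifest, SegMask, load_mask, load_slice
from .losses import multitask_loss_grad
from .metrics import segmentation_scores
from .model import MUNet
from .phantom import CLASS_INDEX, CLASS_NAMES, ClassLabel
from .preprocess import to_network_input

_log = logging.getLogger("ihsnet")


@dataclass
class TrainConfig:
    input_size: int = 256
    learning_rate: float = 1e-4
    lr_drop_factor: float = 0.5
    epochs: int = 60
    batch_size: int = 32
    optimizer: str = "adam"
    seed: int = 0
    patience: int = 5
    val_fraction: float = 0.1
    min_delta: float = 1e-4
    loss_lambda: float = 1.0
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    dice_smooth: float = 1.0
    dice_mode: str = "image"
    #: select the checkpointed model by "loss" (default) or "accuracy"
    best_by: str = "loss"

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.best_by not in ("loss", "accuracy"):
            raise ValueError(f"best_by must be 'loss' or 'accuracy'")


@dataclass
class TrainHistory:
    """Per-epoch curves; lengths equal the number of epochs run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_pixel_acc: list[float] = field(default_factory=list)
    val_pixel_acc: list[float] = field(default_factory=list)
    train_cls_acc: list[float] = field(default_factory=list)
    val_cls_acc: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    checkpoint_path: str | None = None


class PlateauScheduler:
    """Multiply the learning rate by ``factor`` after ``patience``
    epochs without a validation-loss improvement of ``min_delta``."""

    def __init__(
        self, lr: float, factor: float = 0.5, patience: int = 5, min_delta: float = 1e-4
    ):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = float("inf")
        self.stale = 0

    def step(self, val_loss: float) -> float:
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.lr *= self.factor
                self.stale = 0
                _log.info("validation plateau: learning rate dropped to %g", self.lr)
        return self.lr


def _load_arrays(frame, input_size: int):
    xs, masks, labels = [], [], []
    for _, row in frame.iterrows():
        ct = load_slice(row["image_path"])
        if ct.height != input_size or ct.width != input_size:
            raise ValueError(
                f"slice {row['image_path']} is {ct.height}x{ct.width}, expected "
                f"{input_size}; preprocess the manifest first"
            )
        xs.append(to_network_input(ct.pixels))
        masks.append(load_mask(row["mask_path"]).labels)
        labels.append(CLASS_INDEX[row["class_name"]])
    return (
        np.stack(xs).astype(np.float32),
        np.stack(masks).astype(np.int64),
        np.asarray(labels, dtype=np.int64),
    )


def train(
    model: MUNet,
    manifest: DatasetManifest,
    cfg: TrainConfig,
    out_dir: str | Path | None = None,
) -> TrainHistory:
    """Optimize the multi-task loss over the manifest's training split.

    Holds out ``val_fraction`` of the training patients as the
    validation set, drops the learning rate on validation plateaus and
    checkpoints the best model (restored into ``model`` on return).
    """
    train_frame = manifest.rows("train")
    if len(train_frame) == 0:
        raise ValueError("manifest has no training rows")

    rng = np.random.default_rng(cfg.seed)
    patients = np.array(sorted(train_frame["patient_id"].unique()))
    rng.shuffle(patients)
    n_val = max(1, int(round(cfg.val_fraction * len(patients)))) if len(patients) > 1 else 0
    val_patients = set(patients[:n_val])
    val_frame = train_frame[train_frame["patient_id"].isin(val_patients)]
    fit_frame = train_frame[~train_frame["patient_id"].isin(val_patients)]
    if len(fit_frame) == 0:
        fit_frame, val_frame = train_frame, train_frame

    x_fit, m_fit, y_fit = _load_arrays(fit_frame, cfg.input_size)
    if len(val_frame):
        x_val, m_val, y_val = _load_arrays(val_frame, cfg.input_size)
    else:
        x_val = m_val = y_val = None

    opt = model.make_optimizer(lr=cfg.learning_rate)
    sched = PlateauScheduler(
        cfg.learning_rate, cfg.lr_drop_factor, cfg.patience, cfg.min_delta
    )
    history = TrainHistory()
    best_state = None
    best_metric = float("inf")

    n = len(x_fit)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_pix, epoch_cls, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, mb, yb = x_fit[idx], m_fit[idx], y_fit[idx]
            seg, cls, _ = model.forward(xb, train=True)
            loss, d_seg, d_cls = multitask_loss_grad(
                cls, seg, yb, mb,
                lam=cfg.loss_lambda, gamma=cfg.focal_gamma, alpha=cfg.focal_alpha,
                smooth=cfg.dice_smooth, dice_mode=cfg.dice_mode,
            )
            if not np.isfinite(loss.total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"L_fl={loss.l_fl}, L_ms={loss.l_ms}"
                )
            opt.zero_grad()
            model.backward(d_seg, d_cls)
            opt.step()
            epoch_loss += loss.total
            epoch_pix += float((seg.argmax(axis=1) == mb).mean())
            epoch_cls += float((cls.argmax(axis=1) == yb).mean())
            n_batches += 1

        history.train_loss.append(epoch_loss / n_batches)
        history.train_pixel_acc.append(epoch_pix / n_batches)
        history.train_cls_acc.append(epoch_cls / n_batches)

        if x_val is not None:
            val_loss, val_pix, val_cls = _evaluate_arrays(model, x_val, m_val, y_val, cfg)
        else:  # no patients to hold out: fall back to the training metrics
            val_loss = history.train_loss[-1]
            val_pix = history.train_pixel_acc[-1]
            val_cls = history.train_cls_acc[-1]
        history.val_loss.append(val_loss)
        history.val_pixel_acc.append(val_pix)
        history.val_cls_acc.append(val_cls)
        history.learning_rate.append(opt.lr)
        _log.info(
            "epoch %d: train loss %.4f, val loss %.4f, val cls acc %.3f, lr %g",
            epoch, history.train_loss[-1], val_loss, val_cls, opt.lr,
        )

        metric = val_loss if cfg.best_by == "loss" else -val_cls
        if history.best_epoch < 0 or metric < best_metric:
            best_metric = metric
            history.best_epoch = epoch
            history.best_val_loss = val_loss
            best_state = {k: v.copy() for k, v in model.state_dict().items()}

        opt.lr = sched.step(val_loss)

    if best_state is not None:
        model.load_state_dict(best_state)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            path = out_dir / "best_model.npz"
            np.savez(path, **best_state)
            history.checkpoint_path = str(path)
    return history


def _evaluate_arrays(model, x, masks, labels, cfg, batch_size: int | None = None):
    """Loss and accuracies over arrays in eval mode (running BN stats)."""
    bs = batch_size or cfg.batch_size
    total_loss, pix_acc, cls_acc, n_batches = 0.0, 0.0, 0.0, 0
    for start in range(0, len(x), bs):
        xb = x[start : start + bs]
        mb = masks[start : start + bs]
        yb = labels[start : start + bs]
        seg, cls, _ = model.forward(xb, train=False)
        loss, _, _ = multitask_loss_grad(
            cls, seg, yb, mb,
            lam=cfg.loss_lambda, gamma=cfg.focal_gamma, alpha=cfg.focal_alpha,
            smooth=cfg.dice_smooth, dice_mode=cfg.dice_mode,
        )
        total_loss += loss.total
        pix_acc += float((seg.argmax(axis=1) == mb).mean())
        cls_acc += float((cls.argmax(axis=1) == yb).mean())
        n_batches += 1
    return total_loss / n_batches, pix_acc / n_batches, cls_acc / n_batches


def predict(
    model: MUNet, ct: CTSlice | np.ndarray
) -> tuple[SegMask, ClassLabel, np.ndarray]:
    """Segment and classify one slice in eval mode.

    Returns the argmax label mask, the argmax class and the class
    probability vector.  Argmax ties break toward the lowest index.
    """
    pixels = ct.pixels if isinstance(ct, CTSlice) else np.asarray(ct)
    if pixels.shape[0] % 32 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(
            f"slice size must be square and divisible by 32, got {pixels.shape}"
        )
    x = to_network_input(pixels)[None]
    seg, cls, _ = model.forward(x, train=False)
    mask = SegMask(labels=seg[0].argmax(axis=0).astype(np.uint8))
    class_idx = int(cls[0].argmax())
    return mask, ClassLabel.from_index(class_idx), cls[0]


def evaluate_model(
    model: MUNet, manifest: DatasetManifest, split: str = "test"
) -> dict:
    """Run the model over a split and collect raw evaluation material:
    truths, predictions, scores, and per-slice per-class Dice/IoU."""
    frame = manifest.rows(split)
    if len(frame) == 0:
        raise ValueError(f"manifest has no rows with split {split!r}")
    truths, preds, scores = [], [], []
    dice_acc: dict[str, list[float]] = {n: [] for n in CLASS_NAMES}
    iou_acc: dict[str, list[float]] = {n: [] for n in CLASS_NAMES}
    for _, row in frame.iterrows():
        ct = load_slice(row["image_path"])
        truth_mask = load_mask(row["mask_path"]).labels
        pred_mask, pred_label, probs = predict(model, ct)
        truths.append(CLASS_INDEX[row["class_name"]])
        preds.append(pred_label.index)
        scores.append(probs)
        per_class = segmentation_scores(pred_mask.labels, truth_mask)
        true_label = CLASS_INDEX[row["class_name"]] + 1
        d, i = per_class[true_label]
        dice_acc[row["class_name"]].append(d)
        iou_acc[row["class_name"]].append(i)
    return {
        "truths": np.asarray(truths),
        "preds": np.asarray(preds),
        "scores": np.stack(scores),
        "dice": {n: float(np.mean(v)) if v else float("nan") for n, v in dice_acc.items()},
        "iou": {n: float(np.mean(v)) if v else float("nan") for n, v in iou_acc.items()},
    }
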