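"""Training loop for the segmentation network.

The regime follows the reference configuration: 100 epochs, learning rate
1e-4, weight decay 1e-4, gradient accumulation over 5 mini-batches per
optimizer update, a checkpoint every 5 epochs.  The soft Dice loss is the
training objective (optionally combined with pixelwise binary
cross-entropy).  Everything is driven by one integer seed: data order,
model weights, and therefore the entire trajectory are bit-reproducible.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .errors import ConfigurationError, InputError
from .nn import AdamW, BatchNorm2d, Tensor, log as t_log, no_grad, tsum
from .phantoms import PhantomSpec, generate_phantom
from .se_resunet import SEResUNet, save_checkpoint

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "train",
    "evaluate",
    "soft_dice_loss_t",
    "phantom_dataset",
    "split_dataset",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults mirror the reference regime)."""

    epochs: int = 100
    lr: float = 1e-4
    weight_decay: float = 1e-4
    accumulation_steps: int = 5
    checkpoint_interval_epochs: int = 5
    batch_size: int = 4
    seed: int = 0
    loss: str = "dice"  # "dice" | "dice+bce"

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.accumulation_steps < 1:
            raise ConfigurationError("epochs, batch_size and accumulation_steps must be >= 1")
        if self.checkpoint_interval_epochs < 1:
            raise ConfigurationError("checkpoint_interval_epochs must be >= 1")
        if self.loss not in ("dice", "dice+bce"):
            raise ConfigurationError(f"unknown loss {self.loss!r}")


@dataclass
class TrainHistory:
    """One row per epoch plus the written checkpoint paths."""

    epochs: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    checkpoints: list[str] = field(default_factory=list)
    optimizer_updates: int = 0


def soft_dice_loss_t(prob: Tensor, ref: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Differentiable soft Dice loss between probabilities and a binary mask."""
    ref = ref.astype(np.float32)
    inter = tsum(prob * ref)
    den = tsum(prob) + float(ref.sum())
    return 1.0 - (2.0 * inter + eps) / (den + eps)


def _bce_loss_t(prob: Tensor, ref: np.ndarray, eps: float = 1e-7) -> Tensor:
    ref = ref.astype(np.float32)
    n = ref.size
    pos = tsum(ref * t_log(prob + eps))
    neg = tsum((1.0 - ref) * t_log(1.0 - prob + eps))
    return (pos + neg) * (-1.0 / n)


def _check_dataset(name: str, dataset) -> tuple[np.ndarray, np.ndarray]:
    try:
        images, masks = dataset
    except (TypeError, ValueError) as exc:
        raise InputError(f"{name} dataset must be an (images, masks) pair") from exc
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks)
    if images.ndim != 4:
        raise InputError(f"{name} images must be (N, C, H, W), got shape {images.shape}")
    if masks.ndim == 4 and masks.shape[1] == 1:
        masks = masks[:, 0]
    if masks.ndim != 3 or masks.shape[0] != images.shape[0]:
        raise InputError(f"{name} masks must be (N, H, W) aligned with images")
    if images.shape[0] == 0:
        raise InputError(f"{name} dataset is empty")
    return images, masks.astype(np.float32)


def train(model: SEResUNet, train_set, val_set, config: TrainConfig = TrainConfig(),
          checkpoint_dir: str | None = None) -> tuple[SEResUNet, TrainHistory]:
    """Fit the model; returns it with a per-epoch :class:`TrainHistory`.

    Gradients are accumulated over ``accumulation_steps`` mini-batches and
    one optimizer update is applied per full accumulation window (a
    trailing partial window carries over; it is never flushed early).
    Checkpoints are written every ``checkpoint_interval_epochs`` epochs
    when ``checkpoint_dir`` is given.
    """
    config.validate()
    x_train, y_train = _check_dataset("train", train_set)
    x_val, y_val = _check_dataset("validation", val_set)

    rng = np.random.default_rng(config.seed)
    optimizer = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    history = TrainHistory()
    n = x_train.shape[0]
    accum = 0

    for epoch in range(1, config.epochs + 1):
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            prob = model(Tensor(x_train[idx]))
            loss = soft_dice_loss_t(prob, y_train[idx][:, None])
            if config.loss == "dice+bce":
                loss = loss + _bce_loss_t(prob, y_train[idx][:, None])
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, mini-batch "
                    f"{start // config.batch_size + 1}"
                )
            epoch_losses.append(loss_val)
            # scale so the applied update is the mean over the window
            (loss * (1.0 / config.accumulation_steps)).backward()
            accum += 1
            if accum == config.accumulation_steps:
                optimizer.step()
                optimizer.zero_grad()
                accum = 0

        report = evaluate(model, (x_val, y_val))
        history.epochs.append(epoch)
        history.loss.append(float(np.mean(epoch_losses)))
        history.val_dice.append(report.dice)
        history.val_accuracy.append(_val_accuracy(model, x_val, y_val))
        logger.info("epoch %d: loss=%.4f val_dice=%.4f", epoch,
                    history.loss[-1], report.dice)

        if checkpoint_dir is not None and epoch % config.checkpoint_interval_epochs == 0:
            os.makedirs(checkpoint_dir, exist_ok=True)
            path = os.path.join(checkpoint_dir, f"epoch_{epoch:04d}.npz")
            save_checkpoint(model, path, extra={"epoch": epoch,
                                                "loss": history.loss[-1]})
            history.checkpoints.append(path)

    history.optimizer_updates = optimizer.step_count
    _recalibrate_batch_norm(model, x_train, config.batch_size)
    return model, history


def _recalibrate_batch_norm(model: SEResUNet, images: np.ndarray, batch: int) -> None:
    """Recompute batch-norm running statistics under the final weights.

    During a short run the exponential running estimates lag the rapidly
    moving weights, so eval-mode behaviour can drift from train-mode
    behaviour.  One pass over the training set with cumulative-average
    momentum (1/k at step k) replaces the stale estimates with the exact
    mean of the per-batch statistics.
    """
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 1.0
    model.train()
    with no_grad():
        for k, start in enumerate(range(0, images.shape[0], batch)):
            for bn in bns:
                bn.momentum = 1.0 / (k + 1)
            model(Tensor(images[start:start + batch]))
    for bn in bns:
        bn.momentum = 0.1
    model.eval()


def _predict_batched(model: SEResUNet, images: np.ndarray, batch: int = 4) -> np.ndarray:
    outs = []
    model.eval()
    with no_grad():
        for start in range(0, images.shape[0], batch):
            outs.append(model(Tensor(images[start:start + batch])).data[:, 0])
    return np.concatenate(outs, axis=0)


def _val_accuracy(model: SEResUNet, x_val: np.ndarray, y_val: np.ndarray,
                  threshold: float = 0.5) -> float:
    probs = _predict_batched(model, x_val)
    pred = (probs >= threshold).astype(np.uint8)
    return float(np.mean(pred == y_val.astype(np.uint8)))


def evaluate(model: SEResUNet, dataset, threshold: float = 0.5) -> _metrics.MetricReport:
    """Mean per-image Dice/IoU/precision/recall plus pixel-pooled AUC."""
    images, masks = _check_dataset("evaluation", dataset)
    probs = _predict_batched(model, images)
    preds = (probs >= threshold).astype(np.uint8)
    refs = masks.astype(np.uint8)

    dices, ious, precs, recs = [], [], [], []
    for p, r in zip(preds, refs):
        dices.append(_metrics.dice_coefficient(p, r))
        ious.append(_metrics.miou(p, r))
        pr, rc = _metrics.precision_recall(p, r)
        precs.append(pr)
        recs.append(rc)

    flat_ref = refs.ravel()
    if flat_ref.min() == flat_ref.max():
        auc = None  # single-class pool: AUC undefined
    else:
        _, auc = _metrics.roc_auc(probs.ravel(), flat_ref)

    dice = float(np.mean(dices))
    return _metrics.MetricReport(
        dice=dice, dice_loss=1.0 - dice, miou=float(np.mean(ious)),
        precision=float(np.mean(precs)), recall=float(np.mean(recs)), auc=auc,
    )


# -- fixture data ---------------------------------------------------------

def phantom_dataset(n: int, size: int = 64, seed: int = 0,
                    spec: PhantomSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Seeded set of phantoms as model-ready tensors.

    Images are replicated to 3 channels and scaled to [0, 1]; masks stay
    binary.  Phantom i uses seed ``seed * 10000 + i`` so sets with
    different base seeds do not overlap.
    """
    spec = spec or PhantomSpec(size=size)
    images = np.empty((n, 3, size, size), dtype=np.float32)
    masks = np.empty((n, size, size), dtype=np.float32)
    for i in range(n):
        img, mask = generate_phantom(spec, seed=seed * 10000 + i)
        images[i] = np.repeat((img.astype(np.float32) / 255.0)[None], 3, axis=0)
        masks[i] = mask
    return images, masks


def split_dataset(images: np.ndarray, masks: np.ndarray, val_fraction: float = 0.2,
                  seed: int = 0):
    """Seeded train/validation split (default 80/20)."""
    n = images.shape[0]
    order = np.random.default_rng(seed).permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise InputError("dataset too small to split; supply more images")
    return ((images[train_idx], masks[train_idx]),
            (images[val_idx], masks[val_idx]))
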