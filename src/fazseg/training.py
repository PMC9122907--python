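"""Training protocol, replicate-training reproducibility, test-set evaluation.

The optimizer is adaptive-moment gradient descent (Adam) with the
published hyperparameters (alpha = 1e-4, beta1 = 0.9, beta2 = 0.99,
epsilon = 1e-7), batch size 5 with per-epoch shuffling, soft dice loss
(or mean squared error), He-normal initialization and early stopping on
the validation loss (min_delta 1e-8, patience 40).  All randomness is
seeded so that repeated runs with the same seed produce identical
training traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .engine import Adam
from .metrics import dice, soft_dice_grad, summarize
from .models import ArchitectureConfig, SegmentationModel, build_model

__all__ = ["TrainConfig", "History", "EvalReport", "train",
           "replicate_training", "evaluate_testset"]

log = logging.getLogger("fazseg.training")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.99          # published value (conventional default is 0.999)
    epsilon: float = 1e-7
    batch_size: int = 5
    shuffle: bool = True
    max_epochs: int = 500
    early_stopping: bool = True
    min_delta: float = 1e-8
    patience: int = 40
    restore_best: bool = True
    loss: str = "dice"           # {"dice", "mse"}
    initializer: str = "he_normal"
    threshold: float = 0.5       # hardening threshold for the dice metric
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.loss not in ("dice", "mse"):
            raise ValueError("loss must be 'dice' or 'mse'")


@dataclass
class History:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    train_dice: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    stopped_epoch: int = 0
    stop_reason: str = "max_epochs"

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss, "val_loss": self.val_loss,
            "train_dice": self.train_dice, "val_dice": self.val_dice,
        })


@dataclass
class EvalReport:
    dice_raw: np.ndarray
    dice_largest: np.ndarray
    n_images_multi_region: int
    n_extra_contours: int
    mean_dice_raw: float
    sd_dice_raw: float
    mean_dice_largest: float
    sd_dice_largest: float

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "dice_raw": self.dice_raw,
            "dice_largest": self.dice_largest,
        })


def _as_pairs(pairs):
    images, masks = pairs
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks)
    if images.ndim != 4:
        raise ValueError("images must be a (N, H, W, C) array")
    if masks.shape != images.shape[:3]:
        raise ValueError("masks must be a (N, H, W) array matching images")
    if images.shape[0] == 0:
        raise ValueError("empty dataset")
    return images, (masks > 0).astype(np.float32)


def _batch_loss_grad(pred, target, loss_kind):
    """Per-sample loss averaged over the batch; gradient w.r.t. pred."""
    n = pred.shape[0]
    grads = np.empty_like(pred)
    total = 0.0
    for i in range(n):
        if loss_kind == "dice":
            l, g = soft_dice_grad(target[i], pred[i])
        else:
            diff = pred[i] - target[i]
            l = float(np.mean(diff ** 2))
            g = (2.0 / diff.size) * diff
        total += l
        grads[i] = g
    return total / n, grads / n


def _epoch_metrics(model, images, masks3, threshold, batch_size, loss_kind):
    losses, dices = [], []
    for s in range(0, len(images), batch_size):
        xb = images[s:s + batch_size]
        tb = masks3[s:s + batch_size]
        pred = model.forward(xb, training=False)
        l, _ = _batch_loss_grad(pred, tb, loss_kind)
        losses.append(l * len(xb))
        prob = pred.mean(axis=-1)
        for i in range(len(xb)):
            hard = (prob[i] >= threshold).astype(np.uint8)
            dices.append(dice((tb[i, ..., 0] > 0.5).astype(np.uint8), hard))
    return float(np.sum(losses) / len(images)), float(np.mean(dices))


def train(model: SegmentationModel, train_pairs, val_pairs,
          config: TrainConfig = None, verbose: bool = False):
    """Fit ``model``; returns ``(model, History)``.

    ``train_pairs`` / ``val_pairs`` are ``(images, masks)`` with images in
    [0, 1], shape (N, H, W, C), and binary masks of shape (N, H, W).
    """
    config = config or TrainConfig()
    x_tr, m_tr = _as_pairs(train_pairs)
    x_va, m_va = _as_pairs(val_pairs)
    cfg = model.config
    if x_tr.shape[1:] != (cfg.input_height, cfg.input_width, cfg.input_channels):
        raise ValueError(
            f"training images {x_tr.shape[1:]} do not match model input "
            f"({cfg.input_height}, {cfg.input_width}, {cfg.input_channels})")

    # masks are replicated to the 3 output channels
    t_tr = np.repeat(m_tr[..., None], 3, axis=-1)
    t_va = np.repeat(m_va[..., None], 3, axis=-1)

    rng = np.random.default_rng(config.seed)
    model.reseed_dropout(config.seed)
    opt = Adam(model.layers(), lr=config.learning_rate, beta1=config.beta1,
               beta2=config.beta2, eps=config.epsilon)

    history = History()
    best_val = np.inf
    best_weights = None
    wait = 0
    n = len(x_tr)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        running_loss, running_dice, nb = 0.0, 0.0, 0
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            xb, tb = x_tr[idx], t_tr[idx]
            pred = model.forward(xb, training=True)
            loss, dpred = _batch_loss_grad(pred, tb, config.loss)
            opt.zero_grad()
            model.backward(dpred.astype(np.float32))
            opt.step()
            running_loss += loss * len(idx)
            prob = pred.mean(axis=-1)
            for i in range(len(idx)):
                hard = (prob[i] >= config.threshold).astype(np.uint8)
                running_dice += dice(
                    (tb[i, ..., 0] > 0.5).astype(np.uint8), hard)
            nb += len(idx)
        train_loss = running_loss / nb
        train_dice = running_dice / nb
        val_loss, val_dice = _epoch_metrics(
            model, x_va, t_va, config.threshold, config.batch_size, config.loss)

        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.train_dice.append(train_dice)
        history.val_dice.append(val_dice)
        history.stopped_epoch = epoch
        msg = (f"epoch {epoch:3d}  loss {train_loss:.4f}  D {train_dice:.4f}  "
               f"val_loss {val_loss:.4f}  val_D {val_dice:.4f}")
        log.info(msg)
        if verbose:
            print(msg)

        if config.early_stopping:
            if val_loss < best_val - config.min_delta:
                best_val = val_loss
                wait = 0
                if config.restore_best:
                    best_weights = model.get_weights()
            else:
                wait += 1
                if wait >= config.patience:
                    history.stop_reason = "early_stop"
                    if config.restore_best and best_weights is not None:
                        model.set_weights(best_weights)
                    break
    return model, history


def evaluate_testset(model: SegmentationModel, pairs,
                     threshold: float = 0.5) -> EvalReport:
    """Table-2-style evaluation: raw dice, largest-region dice, extras.

    For each image the prediction is binarized, the dice against the
    ground truth recorded, 8-connected regions are counted, and a second
    dice is computed after keeping only the largest region (holes
    filled).
    """
    images, masks = _as_pairs(pairs)
    d_raw, d_big = [], []
    multi, extras = 0, 0
    structure = np.ones((3, 3), dtype=int)
    for i in range(len(images)):
        prob = model.predict(images[i:i + 1])[0, ..., 0]
        hard = (prob >= threshold).astype(np.uint8)
        gt = masks[i].astype(np.uint8)
        d_raw.append(dice(gt, hard))
        lab, n_reg = ndimage.label(hard, structure=structure)
        if n_reg > 1:
            multi += 1
            extras += n_reg - 1
        if n_reg >= 1:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                       index=np.arange(1, n_reg + 1))
            keep = int(np.argmax(sizes)) + 1
            big = ndimage.binary_fill_holes(lab == keep).astype(np.uint8)
        else:
            big = hard
        d_big.append(dice(gt, big))
    mean_r, sd_r = summarize(d_raw) if len(d_raw) > 1 else (d_raw[0], 0.0)
    mean_b, sd_b = summarize(d_big) if len(d_big) > 1 else (d_big[0], 0.0)
    return EvalReport(
        dice_raw=np.asarray(d_raw), dice_largest=np.asarray(d_big),
        n_images_multi_region=multi, n_extra_contours=extras,
        mean_dice_raw=mean_r, sd_dice_raw=sd_r,
        mean_dice_largest=mean_b, sd_dice_largest=sd_b)


def replicate_training(arch: "ArchitectureConfig | str",
                       config: TrainConfig, n_repeats: int,
                       train_pairs, val_pairs, test_pairs,
                       input_size: Optional[tuple] = None) -> dict:
    """Train the same architecture ``n_repeats`` times with distinct seeds.

    Repeats differ only in the per-repeat seed stream
    (``config.seed + repeat index``, applied to both initialization and
    shuffling).  Returns per-repeat mean test dice plus the five-number
    summary used for boxplots.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    per_repeat = []
    seeds = []
    for r in range(n_repeats):
        seed = config.seed + r
        seeds.append(seed)
        model = build_model(arch, seed=seed, input_size=input_size)
        cfg_r = TrainConfig(**{**config.__dict__, "seed": seed})
        model, hist = train(model, train_pairs, val_pairs, cfg_r)
        report = evaluate_testset(model, test_pairs, threshold=config.threshold)
        per_repeat.append(report.mean_dice_raw)
        log.info("repeat %d (seed %d): mean test D = %.4f",
                 r, seed, report.mean_dice_raw)
    vals = np.asarray(per_repeat)
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {
        "per_repeat_mean_dice": per_repeat,
        "seeds": seeds,
        "min": float(vals.min()), "max": float(vals.max()),
        "q1": float(q1), "median": float(med), "q3": float(q3),
        "iqr": float(q3 - q1),
        "spread": float(vals.max() - vals.min()),
    }
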