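"""Dice-loss training of the U-Net on extracted patch sets.

Optimization is plain mini-batch SGD with momentum: the learning rate starts
at 1e-3, is held for 60 epochs, then stepped down by a factor of 10 for the
remaining epochs of the 100-epoch schedule. The loss is the smoothed
multi-class soft Dice, macro-averaged over the four tissue classes, which
keeps the dominant background class from swamping the rare tumor classes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .io_preprocess import brats_to_contiguous
from .model import UNet3D
from .patch_sampler import PatchSet


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters; defaults are the reference schedule."""

    lr: float = 0.001
    decay_epoch: int = 60
    decay_factor: float = 0.1
    epochs: int = 100
    batch_size: int = 8
    momentum: float = 0.9
    dropout: float = 0.25
    rng_seed: int = 0
    smooth: float = 1e-5
    ce_weight: float = 0.0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError(f"learning rate must be positive, got {self.lr}")
        if not 0 < self.decay_factor < 1:
            raise ValueError(f"decay factor must be in (0, 1), got {self.decay_factor}")
        if not 0 < self.decay_epoch < self.epochs:
            raise ValueError(
                f"decay epoch {self.decay_epoch} must lie inside 1..{self.epochs - 1}"
            )
        if self.smooth <= 0:
            raise ValueError("smoothing constant must be positive")
        if self.ce_weight < 0:
            raise ValueError("cross-entropy weight must be >= 0")


@dataclass(frozen=True)
class EpochStats:
    epoch: int
    lr: float
    mean_loss: float


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Learning rate for a 1-based epoch: held until the decay epoch
    (inclusive), then stepped down once by the decay factor."""
    if not 1 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} outside schedule 1..{config.epochs}")
    if epoch <= config.decay_epoch:
        return config.lr
    return config.lr * config.decay_factor


def one_hot(labels: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """Contiguous class labels (N, D, H, W) -> one-hot (N, C, D, H, W)."""
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def _dice_per_class(probs: np.ndarray, truth: np.ndarray, smooth: float):
    """Soft Dice per (sample, class); inputs (N, C, spatial...)."""
    sp = tuple(range(2, probs.ndim))
    inter = (probs * truth).sum(axis=sp, dtype=np.float64)
    sums = probs.sum(axis=sp, dtype=np.float64) + truth.sum(axis=sp, dtype=np.float64)
    return (2.0 * inter + smooth) / (sums + smooth), sums


def dice_loss(probs: np.ndarray, truth: np.ndarray, smooth: float = 1e-5) -> float:
    """1 minus the mean over classes (and samples) of smoothed soft Dice.

    ``probs`` are per-voxel class probabilities, ``truth`` the matching
    one-hot labels; both (N, C, D, H, W) or (C, D, H, W). The value lies
    in [0, 1]: 0 for a perfect prediction, near 1 for a total miss.
    """
    if probs.shape != truth.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs truth {truth.shape}")
    if probs.ndim == 4:
        probs, truth = probs[None], truth[None]
    ds, _ = _dice_per_class(probs, truth, smooth)
    return float(1.0 - ds.mean())


def dice_loss_grad(probs: np.ndarray, truth: np.ndarray, smooth: float = 1e-5) -> np.ndarray:
    """Gradient of :func:`dice_loss` with respect to the probabilities."""
    squeeze = probs.ndim == 4
    if squeeze:
        probs, truth = probs[None], truth[None]
    n, c = probs.shape[:2]
    sp = tuple(range(2, probs.ndim))
    inter = (probs * truth).sum(axis=sp, dtype=np.float64)
    sums = probs.sum(axis=sp, dtype=np.float64) + truth.sum(axis=sp, dtype=np.float64)
    num = 2.0 * inter + smooth
    den = sums + smooth
    shape = (n, c) + (1,) * len(sp)
    g = -(2.0 * truth * den.reshape(shape) - num.reshape(shape)) / (den ** 2).reshape(shape)
    g /= n * c
    g = g.astype(np.float32)
    return g[0] if squeeze else g


def cross_entropy_grad(probs: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Gradient of voxel-mean cross-entropy w.r.t. the probabilities.

    Through the softmax this contributes (p - t) per voxel, which does not
    vanish when a class's probability collapses — pure soft-Dice gradients
    do (they are scaled by p through the softmax), so a rare class that
    saturates early can never recover. A small admixture of this term
    (``TrainConfig.ce_weight``) keeps every class trainable; with weight 0
    the optimization is pure Dice.
    """
    n = probs.shape[0] * int(np.prod(probs.shape[2:]))
    return (-truth / np.maximum(probs, 1e-7) / n).astype(np.float32)


def sgd_step(model: UNet3D, lr: float, momentum: float) -> None:
    """One SGD-with-momentum update over every trainable parameter."""
    for layer in model.param_layers():
        if not hasattr(layer, "_velocity"):
            layer._velocity = {}
        for name, p, g in layer.params_and_grads():
            v = layer._velocity.get(name)
            if v is None:
                v = np.zeros_like(p)
            v = momentum * v - lr * g
            layer._velocity[name] = v
            p += v


def train(model: UNet3D, patches: PatchSet,
          config: TrainConfig | None = None) -> tuple[UNet3D, list[EpochStats]]:
    """Train in place on a patch set; returns the model and per-epoch history.

    Patches are shuffled every epoch with a generator seeded from the
    config, so two runs with identical inputs produce identical loss
    histories on the same machine.
    """
    config = config or TrainConfig()
    if len(patches) == 0:
        raise ValueError("cannot train on an empty patch set")
    if patches.labels is None:
        raise ValueError("training requires label patches")
    labels = brats_to_contiguous(patches.labels)
    n_classes = model.config.out_classes
    rng = np.random.default_rng(config.rng_seed)
    history: list[EpochStats] = []
    for epoch in range(1, config.epochs + 1):
        lr = lr_schedule(epoch, config)
        perm = rng.permutation(len(patches))
        losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start:start + config.batch_size]
            x = patches.images[idx]
            t = one_hot(labels[idx], n_classes)
            p = model.forward(x, train=True, rng=rng)
            losses.append(dice_loss(p, t, config.smooth))
            gp = dice_loss_grad(p, t, config.smooth)
            if config.ce_weight > 0:
                gp = gp + config.ce_weight * cross_entropy_grad(p, t)
            model.backward(gp)
            sgd_step(model, lr, config.momentum)
        history.append(EpochStats(epoch, lr, float(np.mean(losses))))
    return model, history


def write_history_csv(history: list[EpochStats], path: str | Path) -> Path:
    """Training log as CSV with columns epoch, lr, mean_loss."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "lr", "mean_loss"])
        for s in history:
            writer.writerow([s.epoch, s.lr, s.mean_loss])
    return path
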