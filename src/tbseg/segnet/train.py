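"""Dice-based training with Adam, a step learning-rate decay, and k-fold
cross-validation.

Defaults follow the reference protocol — 2000 epochs, initial learning
rate 1e-4, decayed by a third every 400 epochs, five folds — but the
epoch count is meant to be overridden for desk-scale runs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from ..errors import TrainingDivergenceError, ValidationError
from ..metrics import MetricsReport, aggregate, evaluate_pair
from ..preprocess import AugmentConfig, HUWindow, augment
from ..volgrid import LabelMap, Volume
from .model import NetConfig, SegModel, binarize, predict

DICE_EPS = 1e-5


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 2000
    initial_lr: float = 1e-4
    decay_factor: float = 1.0 / 3.0
    decay_every: int = 400
    folds: int = 5
    batch_size: int = 2
    fg_crop_prob: float = 0.5
    patches_per_volume: int = 1
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    window: HUWindow = field(default_factory=HUWindow)

    def __post_init__(self):
        if self.epochs < 0:
            raise ValidationError(f"epochs must be >= 0, got {self.epochs}")
        if not (0.0 < self.decay_factor <= 1.0):
            raise ValidationError(f"decay_factor must be in (0,1], got {self.decay_factor}")
        if self.decay_every < 1:
            raise ValidationError(f"decay_every must be >= 1, got {self.decay_every}")
        if self.batch_size < 1:
            raise ValidationError(f"batch_size must be >= 1, got {self.batch_size}")
        if not (0.0 <= self.fg_crop_prob <= 1.0):
            raise ValidationError(f"fg_crop_prob must be in [0,1], got {self.fg_crop_prob}")
        if self.patches_per_volume < 1:
            raise ValidationError(f"patches_per_volume must be >= 1, got {self.patches_per_volume}")


def learning_rate(config: TrainConfig, epoch: int) -> float:
    """Piecewise-constant step decay: lr * factor^floor(epoch/decay_every)."""
    return config.initial_lr * config.decay_factor ** (epoch // config.decay_every)


def soft_dice_loss(
    probabilities: np.ndarray, reference: np.ndarray, eps: float = DICE_EPS
) -> float:
    """1 - (2 sum(p*r) + eps) / (sum(p) + sum(r) + eps)."""
    p = np.asarray(probabilities, dtype=np.float64)
    r = np.asarray(reference, dtype=np.float64)
    if p.shape != r.shape:
        raise ValidationError(f"shape mismatch: {p.shape} vs {r.shape}")
    num = 2.0 * float((p * r).sum()) + eps
    den = float(p.sum()) + float(r.sum()) + eps
    return 1.0 - num / den


def soft_dice_loss_grad(
    probabilities: np.ndarray, reference: np.ndarray, eps: float = DICE_EPS
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the probabilities."""
    p = np.asarray(probabilities, dtype=np.float64)
    r = np.asarray(reference, dtype=np.float64)
    if p.shape != r.shape:
        raise ValidationError(f"shape mismatch: {p.shape} vs {r.shape}")
    num = 2.0 * float((p * r).sum()) + eps
    den = float(p.sum()) + float(r.sum()) + eps
    loss = 1.0 - num / den
    grad = -(2.0 * r * den - num) / den**2
    return loss, grad.astype(np.float32)


class Adam:
    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= np.float32(lr) * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def _random_crop(
    volume: Volume,
    label: LabelMap,
    patch: tuple[int, int, int],
    rng: np.random.Generator,
    fg_prob: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Random patch, biased to center on a foreground voxel with ``fg_prob``.

    Foreground-biased sampling counters the extreme class imbalance of
    small structures, which otherwise stalls the Dice loss.
    """
    shape = volume.shape
    if rng.random() < fg_prob and label.mask.any():
        fg = np.argwhere(label.mask)
        center = fg[rng.integers(len(fg))]
        starts = [
            int(np.clip(c - p // 2, 0, max(0, n - p)))
            for c, p, n in zip(center, patch, shape)
        ]
    else:
        starts = [0 if n <= p else int(rng.integers(0, n - p + 1)) for n, p in zip(shape, patch)]
    sl = tuple(slice(s, s + min(p, n)) for s, p, n in zip(starts, patch, shape))
    return volume.values[sl], label.mask[sl]


def train(
    model: SegModel,
    dataset: list[tuple[Volume, LabelMap]],
    config: TrainConfig,
) -> SegModel:
    """Train in place and return the model.

    Volumes must already be preprocessed to [0, 1].  Each epoch applies
    the augmentation policy per sample, crops a (seeded) random patch if
    the volume exceeds the model's patch shape, accumulates soft-Dice
    gradients over mini-batches, and performs Adam updates with the step
    learning-rate decay.  Deterministic for a fixed seed.
    """
    if not dataset:
        raise ValidationError("training dataset is empty")
    for vol, lab in dataset:
        if vol.shape != lab.shape:
            raise ValidationError("volume/label shape mismatch in dataset")
    if config.epochs == 0:
        return model

    patch = model.net_config.patch_shape
    optimizer = Adam(model.net.params())
    for epoch in range(config.epochs):
        lr = learning_rate(config, epoch)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(20, epoch))
        )
        order = rng.permutation(np.repeat(np.arange(len(dataset)), config.patches_per_volume))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            model.net.zero_grads()
            for idx in batch:
                vol, lab = dataset[idx]
                vol, lab = augment(vol, lab, config.augment, epoch, sample_index=int(idx))
                x, r = _random_crop(vol, lab, patch, rng, config.fg_crop_prob)
                p = model.net.forward(x[None].astype(np.float32))
                loss, gp = soft_dice_loss_grad(p[0], r)
                if not np.isfinite(loss):
                    raise TrainingDivergenceError(epoch, loss)
                model.net.backward(gp[None] / len(batch))
                epoch_losses.append(loss)
            optimizer.step(model.net.grads(), lr)
        mean_loss = float(np.mean(epoch_losses))
        model.training_curve.append((mean_loss, 1.0 - mean_loss))
    return model


@dataclass
class FoldResult:
    fold: int
    test_indices: list[int]
    reports: list[MetricsReport]
    summary: dict[str, float]
    model: SegModel | None = None


def kfold_partition(n: int, folds: int, seed: int = 0) -> list[list[int]]:
    """Disjoint, seed-reproducible parts whose union is range(n)."""
    if folds < 2:
        raise ValidationError(f"folds must be >= 2, got {folds}")
    if folds > n:
        raise ValidationError(f"folds ({folds}) exceeds dataset size ({n})")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(30,)))
    order = rng.permutation(n)
    return [sorted(int(i) for i in order[f::folds]) for f in range(folds)]


def cross_validate(
    dataset: list[tuple[Volume, LabelMap]],
    net_config: NetConfig,
    train_config: TrainConfig,
    structure_name: str = "inner_ear",
    threshold: float = 0.5,
    keep_models: bool = False,
) -> tuple[list[FoldResult], dict[str, float]]:
    """Train on folds-1 parts, evaluate on the held-out part, per fold.

    Returns the per-fold results and the mean summary over all held-out
    reports.
    """
    from .model import build_model  # local: keep module import-light

    parts = kfold_partition(len(dataset), train_config.folds, seed=train_config.seed)
    results = []
    all_reports = []
    for f, test_idx in enumerate(parts):
        train_data = [dataset[i] for i in range(len(dataset)) if i not in set(test_idx)]
        model = build_model(net_config, seed=train_config.seed + f, structure_name=structure_name)
        model = train(model, train_data, train_config)
        reports = []
        for i in test_idx:
            vol, ref = dataset[i]
            t0 = time.perf_counter()
            pred = binarize(predict(model, vol), threshold)
            elapsed = time.perf_counter() - t0
            reports.append(evaluate_pair(pred, ref, elapsed))
        all_reports.extend(reports)
        results.append(
            FoldResult(
                fold=f,
                test_indices=list(test_idx),
                reports=reports,
                summary=aggregate(reports),
                model=model if keep_models else None,
            )
        )
    return results, aggregate(all_reports)
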