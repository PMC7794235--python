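"""Pre-transforms: HU windowing to [0,1], side standardization, augmentation.

Training volumes are intensity-rescaled by clamping a fixed HU window to
[0, 1], all cases are standardized to right-sided, and two augmentations
are applied per epoch: a single global intensity jitter factor and a
synchronized left-right flip of volume and label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .volgrid import LabelMap, Volume, flip_lr

#: Default rescale window: -500 .. 2000 HU -> 0 .. 1.
DEFAULT_WINDOW_LO = -500.0
DEFAULT_WINDOW_HI = 2000.0


@dataclass(frozen=True)
class HUWindow:
    lo: float = DEFAULT_WINDOW_LO
    hi: float = DEFAULT_WINDOW_HI

    def __post_init__(self):
        if not (self.lo < self.hi):
            raise ValidationError(f"HUWindow requires lo < hi, got ({self.lo}, {self.hi})")


@dataclass(frozen=True)
class AugmentConfig:
    """Per-epoch augmentation policy.

    ``jitter_prob``: chance that the whole volume's intensities are
    multiplied by one factor drawn uniformly from
    ``[1 - jitter_magnitude, 1 + jitter_magnitude]`` (then re-clamped to
    [0, 1]).  ``flip_prob``: chance of a synchronized left-right flip.
    """

    jitter_prob: float = 0.1
    jitter_magnitude: float = 0.1
    flip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("jitter_prob", "flip_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {p}")
        if self.jitter_magnitude < 0:
            raise ValidationError(f"jitter_magnitude must be >= 0, got {self.jitter_magnitude}")


def window_rescale(volume: Volume, window: HUWindow | None = None) -> Volume:
    """Map HU linearly onto [0, 1], clamping outside the window."""
    window = window or HUWindow()
    v = np.asarray(volume.values, dtype=np.float32)
    out = np.clip((v - window.lo) / (window.hi - window.lo), 0.0, 1.0)
    return volume.with_values(out)


def standardize_side(
    volume: Volume,
    label: LabelMap | None = None,
    source_side: str = "right",
) -> tuple[Volume, LabelMap | None, bool]:
    """Make every case right-sided: mirror left-sided inputs.

    Returns ``(volume, label, flipped)``.  Idempotent by contract: the
    output is right-sided, so standardizing again is a no-op.
    """
    if source_side not in ("left", "right"):
        raise ValidationError(f"source_side must be 'left' or 'right', got {source_side!r}")
    if source_side == "right":
        return volume, label, False
    return flip_lr(volume), None if label is None else flip_lr(label), True


def _draws(config: AugmentConfig, epoch: int, sample_index: int) -> tuple[float, float, float]:
    """Reproducible (jitter activation, jitter factor, flip activation) draws."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(int(epoch), int(sample_index)))
    )
    u_jitter = rng.random()
    factor = 1.0 + config.jitter_magnitude * (2.0 * rng.random() - 1.0)
    u_flip = rng.random()
    return u_jitter, factor, u_flip


def jitter_factor(config: AugmentConfig, epoch: int, sample_index: int = 0) -> float:
    """The intensity factor that :func:`augment` would apply (always drawn)."""
    return _draws(config, epoch, sample_index)[1]


def augment(
    volume: Volume,
    label: LabelMap,
    config: AugmentConfig,
    epoch: int,
    sample_index: int = 0,
) -> tuple[Volume, LabelMap]:
    """Apply the per-epoch augmentations; volume must be window-rescaled.

    Randomness is keyed by ``(config.seed, epoch, sample_index)`` so
    repeated calls with identical keys return identical results.
    """
    u_jitter, factor, u_flip = _draws(config, epoch, sample_index)
    out_vol, out_lab = volume, label
    if u_jitter < config.jitter_prob:
        jittered = np.clip(out_vol.values * np.float32(factor), 0.0, 1.0)
        out_vol = out_vol.with_values(jittered)
    if u_flip < config.flip_prob:
        out_vol = flip_lr(out_vol)
        out_lab = flip_lr(out_lab)
    return out_vol, out_lab
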