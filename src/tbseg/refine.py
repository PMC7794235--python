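"""Post-prediction refinement: HU-constrained margin maximization
(shrink then grow), island exclusion, and otic-capsule derivation.

Refinement works on the raw-HU volume (never the windowed one).
Out-of-range labelled voxels are removed first so they cannot seed
growth; small disconnected islands are excluded both before growth (so
stray false positives cannot flood a neighbouring same-range structure)
and after it.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volgrid import LabelMap, Volume, isotropic_spec, require_same_grid, resample

log = logging.getLogger(__name__)

#: Default working spacing for refinement (mm, isotropic).
WORKING_SPACING_MM = 0.25

#: Default cap on growth iterations (~12.5 mm reach at 0.25 mm spacing).
MAX_GROW_ITERATIONS = 50


@dataclass(frozen=True)
class HURange:
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValidationError(f"HURange requires lo <= hi, got ({self.lo}, {self.hi})")

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of voxels inside the (inclusive) range."""
        return (values >= self.lo) & (values <= self.hi)


@dataclass(frozen=True)
class IslandPolicy:
    """Either keep the single largest component or drop components < min_size."""

    keep_largest: bool = True
    min_size: int | None = None

    def __post_init__(self):
        if self.min_size is not None and self.min_size < 1:
            raise ValidationError(f"min_size must be >= 1, got {self.min_size}")
        if not self.keep_largest and self.min_size is None:
            raise ValidationError("island policy needs keep_largest or min_size")


@dataclass(frozen=True)
class StructureSpec:
    name: str
    refine_range: HURange
    island_policy: IslandPolicy = field(default_factory=IslandPolicy)
    max_grow_iterations: int = MAX_GROW_ITERATIONS
    grow_connectivity: str = "faces"  # 'faces' (6) or 'all_neighbors' (26)

    def __post_init__(self):
        if self.max_grow_iterations < 0:
            raise ValidationError("max_grow_iterations must be >= 0")
        if self.grow_connectivity not in ("faces", "all_neighbors"):
            raise ValidationError(f"unknown grow_connectivity {self.grow_connectivity!r}")


_SOFT = HURange(-400.0, 550.0)

#: Default per-structure refinement table.  The sigmoid sinus range is an
#: assumption (soft tissue) and is meant to be overridden from config.
DEFAULT_STRUCTURES: dict[str, StructureSpec] = {
    "inner_ear": StructureSpec("inner_ear", _SOFT),
    "facial_nerve": StructureSpec("facial_nerve", _SOFT),
    "ossicles": StructureSpec("ossicles", HURange(100.0, 2500.0)),
    "sigmoid_sinus": StructureSpec("sigmoid_sinus", _SOFT),
    "otic_capsule": StructureSpec("otic_capsule", HURange(650.0, 2500.0)),
}

OTIC_CAPSULE_RANGE = HURange(650.0, 2500.0)


def _structure(connectivity: str) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == "faces" else 3)


def _grow(mask: np.ndarray, allowed: np.ndarray, struct: np.ndarray, max_iter: int) -> np.ndarray:
    for _ in range(max_iter):
        grown = ndimage.binary_dilation(mask, structure=struct) & allowed
        if np.array_equal(grown, mask):
            break
        mask = grown
    return mask


def hu_constrained_refine(label: LabelMap, volume: Volume, spec: StructureSpec) -> LabelMap:
    """Shrink the label to its in-range voxels, then grow within range.

    Every output voxel has HU inside ``spec.refine_range``.  With a
    large enough iteration cap this equals a flood fill of the in-range
    region seeded by the in-range subset of the input label, and the op
    is idempotent.
    """
    require_same_grid(label, volume)
    in_range = spec.refine_range.contains(volume.values)
    mask = label.mask & in_range  # shrink first: out-of-range voxels must not seed growth
    mask = _grow(mask, in_range, _structure(spec.grow_connectivity), spec.max_grow_iterations)
    return label.with_mask(mask)


def remove_islands(label: LabelMap, policy: IslandPolicy) -> LabelMap:
    """Drop small disconnected components (26-connectivity).

    ``keep_largest`` retains exactly the maximal component (ties broken
    by the component containing the smallest linear voxel index);
    ``min_size`` retains every component of at least that many voxels.
    """
    mask = label.mask
    if not mask.any():
        return label.with_mask(mask.copy())
    comp, n = ndimage.label(mask, structure=_structure("all_neighbors"))
    if n <= 1 and policy.keep_largest and policy.min_size is None:
        return label.with_mask(mask.copy())
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    if policy.min_size is not None:
        keep = sizes >= policy.min_size
    else:
        biggest = sizes.max()
        candidates = np.flatnonzero(sizes == biggest)
        if candidates.size > 1:
            flat = comp.ravel()
            first = {c: np.flatnonzero(flat == c)[0] for c in candidates}
            winner = min(candidates, key=lambda c: first[c])
        else:
            winner = candidates[0]
        keep = np.zeros_like(sizes, dtype=bool)
        keep[winner] = True
    return label.with_mask(keep[comp])


def refine_pipeline(
    prob_or_label: Volume | LabelMap,
    volume: Volume,
    spec: StructureSpec,
    working_spacing: float = WORKING_SPACING_MM,
    threshold: float = 0.5,
) -> LabelMap:
    """Full post-processing chain on one structure.

    Resamples to an isotropic working grid (volume continuously, mask
    nearest), shrinks to in-range voxels, removes islands, grows within
    the HU range, removes islands again, and resamples the mask back to
    the input grid.

    The island pass before growth is load-bearing: a stray false-positive
    voxel inside another same-HU-range structure would otherwise seed a
    flood of that structure and can out-grow the true one.
    """
    if isinstance(prob_or_label, LabelMap):
        mask = prob_or_label
    else:
        from .segnet import binarize  # local import; avoids cycle

        mask = binarize(prob_or_label, threshold)
    require_same_grid(mask, volume)
    original = mask.grid
    work = isotropic_spec(original, working_spacing)
    vol_w = resample(volume, work, mode="continuous")
    mask_w = resample(mask, work, mode="nearest")
    shrink_only = dataclasses.replace(spec, max_grow_iterations=0)
    refined = hu_constrained_refine(mask_w, vol_w, shrink_only)
    refined = remove_islands(refined, spec.island_policy)
    refined = hu_constrained_refine(refined, vol_w, spec)
    refined = remove_islands(refined, spec.island_policy)
    back = resample(refined, original, mode="nearest")
    # restore the exact input grid metadata (resample round-trip preserves it)
    return mask.with_mask(back.mask)


def derive_otic_capsule(
    inner_ear: LabelMap,
    volume: Volume,
    hu_range: HURange = OTIC_CAPSULE_RANGE,
    max_iterations: int = MAX_GROW_ITERATIONS,
    connectivity: str = "faces",
) -> LabelMap:
    """Grow the compact-bone shell around a refined inner-ear label.

    Seeds are the in-range voxels grow-connected to the inner ear; the
    seed set then grows within the HU range, never entering the inner
    ear itself.  ``max_iterations=0`` returns just the first shell.
    """
    require_same_grid(inner_ear, volume)
    if max_iterations < 0:
        raise ValidationError("max_iterations must be >= 0")
    if inner_ear.voxel_count == 0:
        log.warning("derive_otic_capsule: empty inner-ear label, returning empty capsule")
        return inner_ear.with_mask(np.zeros(inner_ear.shape, dtype=bool))
    struct = _structure(connectivity)
    in_range = hu_range.contains(volume.values) & ~inner_ear.mask
    seed = ndimage.binary_dilation(inner_ear.mask, structure=struct) & in_range
    capsule = _grow(seed, in_range, struct, max_iterations)
    return inner_ear.with_mask(capsule)
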