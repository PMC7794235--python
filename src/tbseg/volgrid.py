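"""Core grid types, NIfTI I/O and geometric resampling.

All grids are kept in a canonical anatomical axis order:

* axis 0: left -> right  (``R``)
* axis 1: posterior -> anterior  (``A``)
* axis 2: inferior -> superior  (``S``)

The world coordinate of voxel index ``(i, j, k)`` is
``origin + index * spacing`` along the canonical axes, where a voxel's
position means its *center*.  Files are reoriented on load so that code
downstream never has to reason about orientation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError, GridMismatchError, ValidationError

CANONICAL_ORIENTATION = "RAS"

#: HU value used to fill out-of-field voxels when resampling a volume (air).
AIR_HU = -1000.0

_DIRECTIONS = {
    "R": np.array([1.0, 0.0, 0.0]),
    "L": np.array([-1.0, 0.0, 0.0]),
    "A": np.array([0.0, 1.0, 0.0]),
    "P": np.array([0.0, -1.0, 0.0]),
    "S": np.array([0.0, 0.0, 1.0]),
    "I": np.array([0.0, 0.0, -1.0]),
}


@dataclass(frozen=True)
class GridSpec:
    """Target geometry for a resampling operation."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self):
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValidationError("GridSpec shape and spacing must be 3-tuples")
        if any(int(n) < 1 for n in self.shape):
            raise ValidationError(f"GridSpec shape must be >= 1 per axis, got {self.shape}")
        if any(not (s > 0) for s in self.spacing):
            raise ValidationError(f"GridSpec spacing must be > 0 per axis, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))


@dataclass
class Volume:
    """A 3D scalar grid (HU-valued, or unitless after windowing)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = CANONICAL_ORIENTATION

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(f"Volume values must be 3D, got ndim={self.values.ndim}")
        if any(n < 1 for n in self.values.shape):
            raise ValidationError("Volume must have >= 1 voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(not (s > 0) for s in self.spacing):
            raise ValidationError(f"spacing must be > 0 per axis, got {self.spacing}")
        n_bad = int(np.count_nonzero(~np.isfinite(self.values)))
        if n_bad:
            raise ValidationError(f"volume contains {n_bad} non-finite voxel(s)")
        _check_orientation(self.orientation)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.shape, self.spacing)

    def with_values(self, values: np.ndarray) -> "Volume":
        """Same grid metadata, new voxel values."""
        return dataclasses.replace(self, values=values)

    def same_grid_as(self, other: "Volume | LabelMap", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and self.orientation == other.orientation
        )


@dataclass
class LabelMap:
    """A binary mask sharing a Volume's grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = CANONICAL_ORIENTATION

    def __post_init__(self):
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValidationError(f"LabelMap mask must be 3D, got ndim={mask.ndim}")
        uniq = np.unique(mask)
        if not np.isin(uniq, (0, 1)).all():
            raise ValidationError(f"LabelMap values must be in {{0,1}}, got {uniq[:10]}")
        self.mask = mask.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(not (s > 0) for s in self.spacing):
            raise ValidationError(f"spacing must be > 0 per axis, got {self.spacing}")
        _check_orientation(self.orientation)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.shape, self.spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def with_mask(self, mask: np.ndarray) -> "LabelMap":
        return dataclasses.replace(self, mask=mask)

    def same_grid_as(self, other: "Volume | LabelMap", atol: float = 1e-6) -> bool:
        return Volume.same_grid_as(self, other, atol=atol)  # type: ignore[arg-type]

    @classmethod
    def like(cls, ref: "Volume | LabelMap", mask: np.ndarray) -> "LabelMap":
        return cls(mask=mask, spacing=ref.spacing, origin=ref.origin, orientation=ref.orientation)


def _check_orientation(orientation: str) -> None:
    if (
        not isinstance(orientation, str)
        or len(orientation) != 3
        or any(c not in _DIRECTIONS for c in orientation)
    ):
        raise ValidationError(f"invalid orientation {orientation!r}")
    axes = {"".join(sorted("RL")): 0, "".join(sorted("PA")): 0, "".join(sorted("IS")): 0}
    for c in orientation:
        key = "".join(sorted("RL" if c in "RL" else "PA" if c in "PA" else "IS"))
        axes[key] += 1
    if any(v != 1 for v in axes.values()):
        raise ValidationError(f"orientation {orientation!r} does not name three distinct anatomical axes")


def lr_axis(orientation: str) -> int:
    """Index of the grid axis running left-right."""
    _check_orientation(orientation)
    for i, c in enumerate(orientation):
        if c in "RL":
            return i
    raise ValidationError(f"orientation {orientation!r} has no left-right axis")  # pragma: no cover


def _affine_from_metadata(spacing, origin, orientation) -> np.ndarray:
    affine = np.eye(4)
    for i, code in enumerate(orientation):
        affine[:3, i] = _DIRECTIONS[code] * spacing[i]
    affine[:3, 3] = origin
    return affine


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI file, reorienting to the canonical RAS axis order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D scalar image, got shape {data.shape}")
    affine = img.affine
    spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    origin = tuple(float(x) for x in affine[:3, 3])
    values = np.asarray(data, dtype=np.float32)
    n_bad = int(np.count_nonzero(~np.isfinite(values)))
    if n_bad:
        raise ValidationError(f"{path}: volume contains {n_bad} non-finite voxel(s)")
    return Volume(values=values, spacing=spacing, origin=origin, orientation=CANONICAL_ORIENTATION)


def read_label(path: str | Path) -> LabelMap:
    """Read a binary label map from NIfTI (values must be 0/1)."""
    vol = read_volume(path)
    return LabelMap(
        mask=np.rint(vol.values).astype(np.uint8),
        spacing=vol.spacing,
        origin=vol.origin,
        orientation=vol.orientation,
    )


def write_volume(obj: Volume | LabelMap, path: str | Path) -> None:
    """Write a Volume (float32) or LabelMap (uint8) as NIfTI-1."""
    path = Path(path)
    affine = _affine_from_metadata(obj.spacing, obj.origin, obj.orientation)
    if isinstance(obj, LabelMap):
        data = obj.mask.astype(np.uint8)
    else:
        data = np.asarray(obj.values, dtype=np.float32)
    img = nib.Nifti1Image(data, affine)
    img.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def resample(obj: Volume | LabelMap, target: GridSpec, mode: str = "continuous"):
    """Resample onto ``target``, preserving the physical field of view.

    Voxel edges of the input and output grids are aligned at the grid
    corner, so the output origin shifts by ``(s_out - s_in) / 2`` per axis.
    ``continuous`` interpolates linearly (out-of-field fill: -1000 HU),
    ``nearest`` copies the nearest input voxel (fill: 0) and is required
    for label maps.
    """
    if mode not in ("continuous", "nearest"):
        raise ValidationError(f"unknown resample mode {mode!r}")
    is_label = isinstance(obj, LabelMap)
    if is_label and mode != "nearest":
        raise ValidationError("label maps must be resampled with mode='nearest'")
    if not isinstance(target, GridSpec):
        target = GridSpec(*target)

    src = obj.mask.astype(np.float32) if is_label else np.asarray(obj.values, dtype=np.float32)
    in_spacing = np.asarray(obj.spacing)
    out_spacing = np.asarray(target.spacing)
    ratio = out_spacing / in_spacing

    # output voxel center j maps to input index (j + 0.5) * ratio - 0.5
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * r - 0.5 for n, r in zip(target.shape, ratio)],
        indexing="ij",
    )
    order = 0 if mode == "nearest" else 1
    cval = 0.0 if is_label else AIR_HU
    out = ndimage.map_coordinates(
        src, np.stack(coords), order=order, mode="constant", cval=cval, prefilter=False
    )
    new_origin = tuple(
        o + 0.5 * (so - si) for o, so, si in zip(obj.origin, out_spacing, in_spacing)
    )
    if is_label:
        return LabelMap(
            mask=out.astype(np.uint8),
            spacing=target.spacing,
            origin=new_origin,
            orientation=obj.orientation,
        )
    return Volume(
        values=out, spacing=target.spacing, origin=new_origin, orientation=obj.orientation
    )


def isotropic_spec(grid: GridSpec, spacing: float) -> GridSpec:
    """GridSpec covering ``grid``'s field of view at isotropic ``spacing``."""
    if not (spacing > 0):
        raise ValidationError(f"spacing must be > 0, got {spacing}")
    shape = tuple(
        max(1, int(np.ceil(n * s / spacing - 1e-9))) for n, s in zip(grid.shape, grid.spacing)
    )
    return GridSpec(shape, (spacing,) * 3)


def flip_lr(obj: Volume | LabelMap):
    """Mirror across the left-right axis; an involution.

    The array is reversed along the LR axis and the orientation code for
    that axis toggles (R <-> L) with the origin moved to the world
    position of the formerly-last voxel, keeping world coordinates of the
    anatomy consistent.
    """
    axis = lr_axis(obj.orientation)
    n = obj.shape[axis]
    code = obj.orientation[axis]
    new_code = "L" if code == "R" else "R"
    orientation = obj.orientation[:axis] + new_code + obj.orientation[axis + 1 :]
    # world position of old index n-1 along the flipped axis becomes index 0
    direction = _DIRECTIONS[code]
    origin = np.asarray(obj.origin) + direction * obj.spacing[axis] * (n - 1)
    origin = tuple(float(x) for x in origin)
    if isinstance(obj, LabelMap):
        return LabelMap(
            mask=np.flip(obj.mask, axis=axis).copy(),
            spacing=obj.spacing,
            origin=origin,
            orientation=orientation,
        )
    return Volume(
        values=np.flip(obj.values, axis=axis).copy(),
        spacing=obj.spacing,
        origin=origin,
        orientation=orientation,
    )


def require_same_grid(a: Volume | LabelMap, b: Volume | LabelMap) -> None:
    if not a.same_grid_as(b):
        raise GridMismatchError(
            f"grids differ: shape {a.shape} vs {b.shape}, spacing {a.spacing} vs {b.spacing}"
        )
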