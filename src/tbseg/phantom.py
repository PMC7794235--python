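"""Procedural temporal-bone-like CT phantoms with exact ground-truth labels.

Each phantom is a trabecular-bone block containing:

* ``inner_ear``     — fluid-filled union of a vestibule spheroid, a helical
  cochlea-analog tube and three orthogonal canal rings;
* ``otic_capsule``  — a compact-bone shell of fixed thickness wrapped
  tightly around the inner ear;
* ``ossicles``      — small compact-bone ellipsoids suspended in an
  air-filled cavity lateral to the labyrinth;
* ``facial_nerve``  — a thin curved soft-tissue tube passing near the
  labyrinth;
* ``sigmoid_sinus`` — a wide curved soft-tissue channel at the posterior.

Tissue HU means are textbook-style values picked so the refinement
threshold ranges separate the tissues: air -1000, fluid 20, soft 40,
trabecular 600, compact 1500.  Trabecular bone deliberately falls in the
gap between the soft-tissue range (-400..550) and the compact-bone range
(650..2500).  Gaussian noise is added to the volume only; labels are the
exact constructed voxel sets.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ValidationError
from .volgrid import GridSpec, LabelMap, Volume, flip_lr

log = logging.getLogger(__name__)

STRUCTURES = ("inner_ear", "otic_capsule", "ossicles", "facial_nerve", "sigmoid_sinus")

DEFAULT_TISSUE_HU = {
    "air": -1000.0,
    "fluid": 20.0,
    "soft": 40.0,
    "trabecular": 600.0,
    "compact": 1500.0,
}


@dataclass(frozen=True)
class PhantomGeometry:
    """All lengths in mm, relative to a 16 mm field of view."""

    center: tuple[float, float, float] = (8.0, 8.0, 8.0)
    vestibule_radii: tuple[float, float, float] = (1.5, 1.2, 1.2)
    cochlea_radius: float = 1.1  # helix radius
    cochlea_tube_radius: float = 0.45
    cochlea_turns: float = 2.0
    cochlea_offset: tuple[float, float, float] = (0.4, 2.2, -1.3)
    canal_radius: float = 2.0  # ring radius of the three canal arcs
    canal_tube_radius: float = 0.4
    capsule_thickness: float = 0.5
    cavity_offset: tuple[float, float, float] = (4.8, 1.6, 0.8)
    cavity_radius: float = 2.0
    ossicle_radii: tuple[float, float, float] = (0.55, 0.4, 0.4)
    nerve_radius: float = 0.4
    nerve_amplitude: float = 0.5
    sinus_radius: float = 1.1


@dataclass(frozen=True)
class Corruption:
    """Degradation recipe for building plausible 'raw prediction' masks."""

    erode_voxels: int = 0
    noise_flip_rate: float = 0.0


@dataclass(frozen=True)
class PhantomConfig:
    grid: GridSpec = field(default_factory=lambda: GridSpec((64, 64, 64), (0.25, 0.25, 0.25)))
    seed: int = 0
    noise_sd: float = 30.0
    tissue_hu: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    side: str = "right"
    corruption: Corruption | None = None

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        hu = self.tissue_hu
        if not (hu["air"] < hu["fluid"] <= hu["soft"] < hu["trabecular"] < hu["compact"]):
            raise ValidationError("tissue HU must be ordered air < fluid <= soft < trabecular < compact")
        g = self.geometry
        min_len = min(
            min(g.vestibule_radii), g.cochlea_tube_radius, g.canal_tube_radius,
            g.capsule_thickness, g.cavity_radius, min(g.ossicle_radii),
            g.nerve_radius, g.sinus_radius,
        )
        if min_len < max(self.grid.spacing):
            raise ValidationError(
                f"smallest geometric feature ({min_len} mm) is below one voxel "
                f"({max(self.grid.spacing)} mm)"
            )


@dataclass
class PhantomSample:
    case_id: str
    volume: Volume
    labels: dict[str, LabelMap]
    side: str
    seed: int
    config: PhantomConfig


def _voxel_centers(grid: GridSpec):
    axes = [np.arange(n, dtype=np.float64) * s for n, s in zip(grid.shape, grid.spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center, radii) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _tube(grid: GridSpec, coords, curve_pts: np.ndarray, radius: float) -> np.ndarray:
    """Voxels within ``radius`` of a polyline (distance to sampled points)."""
    mask = np.zeros(grid.shape, dtype=bool)
    lo = curve_pts.min(axis=0) - radius - 0.5
    hi = curve_pts.max(axis=0) + radius + 0.5
    sl = tuple(
        slice(max(0, int(np.floor(l / s))), min(n, int(np.ceil(h / s)) + 1))
        for l, h, s, n in zip(lo, hi, grid.spacing, grid.shape)
    )
    pts = np.stack([c[sl].ravel() for c in coords], axis=1)
    if pts.size == 0:
        return mask
    d, _ = cKDTree(curve_pts).query(pts, k=1)
    mask[sl] = (d <= radius).reshape(coords[0][sl].shape)
    return mask


def _canal_rings(g: PhantomGeometry) -> list[np.ndarray]:
    """Three orthogonal rings, each passing through the labyrinth center."""
    c = np.asarray(g.center)
    planes = [
        ((-1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),  # lateral canal, axial plane, medial
        ((0.0, 0.0, 1.0), (0.0, -1.0, 0.0)),  # superior canal
        ((0.0, -1.0, 0.0), (0.0, 0.0, 1.0)),  # posterior canal
    ]
    theta = np.linspace(0.0, 2 * np.pi, 240, endpoint=False)[:, None]
    rings = []
    for u, v in planes:
        u, v = np.asarray(u), np.asarray(v)
        ring_center = c + g.canal_radius * u
        rings.append(ring_center + g.canal_radius * (np.cos(theta) * u + np.sin(theta) * v))
    return rings


def _cochlea_curve(g: PhantomGeometry) -> np.ndarray:
    c = np.asarray(g.center) + np.asarray(g.cochlea_offset)
    t = np.linspace(0.0, 2 * np.pi * g.cochlea_turns, 300)
    frac = t / t[-1]
    r = g.cochlea_radius * (1.0 - 0.45 * frac)
    return np.stack(
        [c[0] + r * np.cos(t), c[1] + r * np.sin(t), c[2] + 0.8 * frac], axis=1
    )


def _nerve_curve(g: PhantomGeometry, extent_z: float) -> np.ndarray:
    c = np.asarray(g.center)
    t = np.linspace(0.0, 1.0, 200)
    z = (0.85 * extent_z) - (0.7 * extent_z) * t
    x = c[0] + 3.0 + g.nerve_amplitude * np.sin(2 * np.pi * t)
    y = c[1] - 1.6 - 0.6 * t
    return np.stack([x, y, z], axis=1)


def _sinus_curve(g: PhantomGeometry, extent: tuple[float, float, float]) -> np.ndarray:
    t = np.linspace(0.0, 1.0, 200)
    z = 0.16 * extent[2] + 0.68 * extent[2] * t
    y = 0.20 * extent[1] + 0.05 * extent[1] * np.sin(np.pi * t)
    x = 0.58 * extent[0] + 0.12 * extent[0] * t
    return np.stack([x, y, z], axis=1)


def _check_inside(name: str, mask: np.ndarray) -> None:
    border = np.zeros(mask.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        border[tuple(sl)] = True
        sl[ax] = -1
        border[tuple(sl)] = True
    if (mask & border).any():
        raise ValidationError(f"phantom structure {name!r} does not fit inside the grid")


def generate_phantom(config: PhantomConfig) -> tuple[Volume, dict[str, LabelMap]]:
    """Build one phantom; deterministic given ``config`` (incl. seed)."""
    grid, g = config.grid, config.geometry
    extent = tuple(n * s for n, s in zip(grid.shape, grid.spacing))
    coords = _voxel_centers(grid)

    inner = _ellipsoid(coords, g.center, g.vestibule_radii)
    inner |= _tube(grid, coords, _cochlea_curve(g), g.cochlea_tube_radius)
    for ring in _canal_rings(g):
        inner |= _tube(grid, coords, ring, g.canal_tube_radius)

    # distance (mm) from the inner ear; the capsule is the thin shell around it
    dist = ndimage.distance_transform_edt(~inner, sampling=grid.spacing)
    capsule = (dist > 0) & (dist <= g.capsule_thickness)
    protected = dist <= g.capsule_thickness + max(grid.spacing)

    cavity = _ellipsoid(
        coords, np.asarray(g.center) + np.asarray(g.cavity_offset), (g.cavity_radius,) * 3
    )
    cavity &= ~protected
    ossicle_centers = np.asarray(g.center) + np.asarray(g.cavity_offset) + np.asarray(
        [[0.0, 0.0, 0.0], [0.9, 0.5, 0.4], [-0.7, -0.5, 0.5]]
    )
    ossicles = np.zeros(grid.shape, dtype=bool)
    for oc in ossicle_centers:
        ossicles |= _ellipsoid(coords, oc, g.ossicle_radii)
    # ossicles live strictly inside the air cavity, clear of the capsule
    ossicles &= cavity & (dist > g.capsule_thickness + 2 * max(grid.spacing))

    nerve = _tube(grid, coords, _nerve_curve(g, extent[2]), g.nerve_radius)
    nerve &= ~protected & ~cavity & ~ossicles
    sinus = _tube(grid, coords, _sinus_curve(g, extent), g.sinus_radius)
    sinus &= ~protected & ~cavity & ~ossicles & ~nerve

    labels_masks = {
        "inner_ear": inner,
        "otic_capsule": capsule,
        "ossicles": ossicles,
        "facial_nerve": nerve,
        "sigmoid_sinus": sinus,
    }
    for name, mask in labels_masks.items():
        _check_inside(name, mask)
    _check_inside("air_cavity", cavity)

    hu = config.tissue_hu
    values = np.full(grid.shape, hu["trabecular"], dtype=np.float32)
    values[cavity] = hu["air"]
    values[sinus] = hu["soft"]
    values[nerve] = hu["soft"]
    values[capsule] = hu["compact"]
    values[inner] = hu["fluid"]
    values[ossicles] = hu["compact"]

    if config.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
        values = values + rng.normal(0.0, config.noise_sd, grid.shape).astype(np.float32)

    volume = Volume(values=values, spacing=grid.spacing)
    labels = {
        name: LabelMap.like(volume, mask.astype(np.uint8)) for name, mask in labels_masks.items()
    }
    if config.side == "left":
        volume = flip_lr(volume)
        labels = {name: flip_lr(lab) for name, lab in labels.items()}
    return volume, labels


def corrupt_label(label: LabelMap, corruption: Corruption, seed: int = 0) -> LabelMap:
    """Erode then sprinkle salt noise: a plausibly degraded raw prediction."""
    mask = label.mask.copy()
    if corruption.erode_voxels > 0:
        mask = ndimage.binary_erosion(
            mask,
            structure=ndimage.generate_binary_structure(3, 1),
            iterations=corruption.erode_voxels,
            border_value=0,
        )
        if not mask.any():
            log.warning("corrupt_label: erosion emptied the mask")
    if corruption.noise_flip_rate > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
        salt = rng.random(mask.shape) < corruption.noise_flip_rate
        mask = mask | (salt & ~mask)
    return label.with_mask(mask)


def _jittered_geometry(g: PhantomGeometry, rng: np.random.Generator, max_spacing: float) -> PhantomGeometry:
    """Radii perturbed +/-20 %, labyrinth placement shifted +/-0.5 mm."""

    def jit(value):
        if isinstance(value, tuple):
            return tuple(v * rng.uniform(0.8, 1.2) for v in value)
        return value * rng.uniform(0.8, 1.2)

    center = tuple(c + rng.uniform(-0.5, 0.5) for c in g.center)
    return dataclasses.replace(
        g,
        center=center,
        vestibule_radii=jit(g.vestibule_radii),
        cochlea_radius=jit(g.cochlea_radius),
        cochlea_tube_radius=jit(g.cochlea_tube_radius),
        canal_radius=jit(g.canal_radius),
        canal_tube_radius=jit(g.canal_tube_radius),
        capsule_thickness=max(jit(g.capsule_thickness), max_spacing),
        cavity_radius=jit(g.cavity_radius),
        ossicle_radii=jit(g.ossicle_radii),
        nerve_radius=jit(g.nerve_radius),
        sinus_radius=jit(g.sinus_radius),
    )


def sample_config(template: PhantomConfig, master_seed: int, index: int) -> PhantomConfig:
    """The i-th per-sample config derived from a dataset master seed."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(2, index)))
    sample_seed = int(rng.integers(0, 2**31 - 1))
    side = "left" if rng.random() < 0.5 else "right"
    geometry = _jittered_geometry(template.geometry, rng, max(template.grid.spacing))
    return dataclasses.replace(template, seed=sample_seed, side=side, geometry=geometry)


def generate_dataset(
    n: int, config_template: PhantomConfig | None = None, seed: int = 0
) -> list[PhantomSample]:
    """n phantoms with per-sample seeds, sides and jittered geometry."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    template = config_template or PhantomConfig()
    samples = []
    for i in range(n):
        cfg = sample_config(template, seed, i)
        volume, labels = generate_phantom(cfg)
        samples.append(
            PhantomSample(
                case_id=f"case_{i:04d}",
                volume=volume,
                labels=labels,
                side=cfg.side,
                seed=cfg.seed,
                config=cfg,
            )
        )
    return samples


def train_test_split(
    samples: list[PhantomSample], n_test: int, seed: int = 0
) -> tuple[list[PhantomSample], list[PhantomSample]]:
    """Seeded random split mirroring a train/test partition."""
    if not (0 < n_test < len(samples)):
        raise ValidationError(f"n_test must be in (0, {len(samples)}), got {n_test}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    order = rng.permutation(len(samples))
    test_idx = set(order[:n_test].tolist())
    train = [s for i, s in enumerate(samples) if i not in test_idx]
    test = [s for i, s in enumerate(samples) if i in test_idx]
    return train, test
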