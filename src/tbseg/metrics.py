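"""Objective validation: Dice coefficient, average Hausdorff distance (mm),
volumetric similarity (%) and per-pair timing.

The average Hausdorff distance is the symmetric average of the two
directed mean nearest-neighbour distances between *boundary* voxels
(voxels with at least one face neighbour outside the mask), measured
between voxel centers in millimetres, so anisotropic spacing is honoured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import UndefinedMetricError, ValidationError
from .volgrid import LabelMap, require_same_grid

_FACES = ndimage.generate_binary_structure(3, 1)


def dice(a: LabelMap, b: LabelMap) -> float:
    """2|A∩B| / (|A| + |B|); 1.0 if both empty, 0.0 if exactly one is."""
    require_same_grid(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.mask & b.mask))
    return 2.0 * inter / (na + nb)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (n, 3) of voxels with a face neighbour outside the mask.

    Voxels on the array border count as boundary (outside is background).
    """
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_FACES, border_value=0)
    return np.argwhere(mask & ~interior)


def average_hausdorff(a: LabelMap, b: LabelMap, use_boundary: bool = True) -> float:
    """Symmetric average of directed mean surface distances, in mm."""
    require_same_grid(a, b)
    if a.voxel_count == 0 or b.voxel_count == 0:
        raise UndefinedMetricError("average Hausdorff distance undefined for empty masks")
    if use_boundary:
        pa, pb = boundary_voxels(a.mask), boundary_voxels(b.mask)
    else:
        pa, pb = np.argwhere(a.mask), np.argwhere(b.mask)
    spacing = np.asarray(a.spacing)
    xa = pa * spacing
    xb = pb * spacing
    d_ab, _ = cKDTree(xb).query(xa, k=1)
    d_ba, _ = cKDTree(xa).query(xb, k=1)
    return 0.5 * (float(np.mean(d_ab)) + float(np.mean(d_ba)))


def volumetric_similarity(pred: LabelMap, ref: LabelMap) -> float:
    """100 * |pred| / |ref| on a shared grid; > 100 means over-segmentation."""
    if not np.allclose(pred.spacing, ref.spacing):
        raise ValidationError("volumetric similarity requires a shared voxel size")
    if ref.voxel_count == 0:
        raise UndefinedMetricError("volumetric similarity undefined for an empty reference")
    return 100.0 * pred.voxel_count / ref.voxel_count


@dataclass
class MetricsReport:
    dsc: float
    ahd_mm: float  # NaN when undefined (an empty mask)
    volumetric_similarity_pct: float  # NaN when reference empty
    seconds: float = float("nan")

    @property
    def ahd_defined(self) -> bool:
        return math.isfinite(self.ahd_mm)

    @property
    def volsim_defined(self) -> bool:
        return math.isfinite(self.volumetric_similarity_pct)


def evaluate_pair(pred: LabelMap, ref: LabelMap, elapsed: float = float("nan")) -> MetricsReport:
    """Bundle the three metrics for one prediction/reference pair.

    Undefined metrics (empty masks) are reported as NaN rather than
    raising, so degenerate cases still yield a row.
    """
    require_same_grid(pred, ref)
    d = dice(pred, ref)
    try:
        ahd = average_hausdorff(pred, ref)
    except UndefinedMetricError:
        ahd = float("nan")
    try:
        # an empty prediction is reported as undefined rather than 0 %:
        # the ratio is degenerate in the same way as an empty reference
        volsim = float("nan") if pred.voxel_count == 0 else volumetric_similarity(pred, ref)
    except UndefinedMetricError:
        volsim = float("nan")
    return MetricsReport(dsc=d, ahd_mm=ahd, volumetric_similarity_pct=volsim, seconds=elapsed)


def aggregate(reports: list[MetricsReport]) -> dict[str, float]:
    """Mean and sample (n-1) SD per metric, NaN-aware, over a list of reports."""
    if not reports:
        raise ValidationError("cannot aggregate an empty report list")

    def _stats(values):
        arr = np.asarray([v for v in values if math.isfinite(v)], dtype=float)
        if arr.size == 0:
            return float("nan"), float("nan")
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        return float(np.mean(arr)), sd

    out: dict[str, float] = {}
    for name, values in (
        ("dsc", [r.dsc for r in reports]),
        ("ahd_mm", [r.ahd_mm for r in reports]),
        ("volsim_pct", [r.volumetric_similarity_pct for r in reports]),
        ("seconds", [r.seconds for r in reports]),
    ):
        mean, sd = _stats(values)
        out[f"{name}_mean"] = mean
        out[f"{name}_sd"] = sd
    return out
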