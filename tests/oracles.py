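"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the production code paths (KD-trees, SciPy
morphology) so that agreement is meaningful: plain double loops and
hand-rolled breadth-first search only.
"""

from __future__ import annotations

import numpy as np

FACE_OFFSETS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
ALL_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def brute_dice(a: np.ndarray, b: np.ndarray) -> float:
    sa = {tuple(i) for i in np.argwhere(a)}
    sb = {tuple(i) for i in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def brute_boundary(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Voxels with at least one face neighbour outside the mask."""
    out = []
    shape = mask.shape
    for idx in np.argwhere(mask):
        i, j, k = (int(x) for x in idx)
        for dz, dy, dx in FACE_OFFSETS:
            ni, nj, nk = i + dz, j + dy, k + dx
            inside = 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]
            if not inside or not mask[ni, nj, nk]:
                out.append((i, j, k))
                break
    return out


def brute_ahd(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """O(|A|*|B|) double loop over boundary voxel centers in mm."""
    spacing = np.asarray(spacing, dtype=float)
    pa = np.asarray(brute_boundary(a), dtype=float) * spacing
    pb = np.asarray(brute_boundary(b), dtype=float) * spacing
    d_ab = [min(float(np.sqrt(((p - q) ** 2).sum())) for q in pb) for p in pa]
    d_ba = [min(float(np.sqrt(((p - q) ** 2).sum())) for q in pa) for p in pb]
    return 0.5 * (sum(d_ab) / len(d_ab) + sum(d_ba) / len(d_ba))


def flood_fill(allowed: np.ndarray, seeds: np.ndarray, connectivity: str = "faces",
               max_steps: int | None = None) -> np.ndarray:
    """BFS over the allowed region from seed voxels (seeds kept only if allowed)."""
    offsets = FACE_OFFSETS if connectivity == "faces" else ALL_OFFSETS
    shape = allowed.shape
    visited = np.zeros(shape, dtype=bool)
    frontier = [tuple(int(x) for x in i) for i in np.argwhere(seeds & allowed)]
    for idx in frontier:
        visited[idx] = True
    steps = 0
    while frontier and (max_steps is None or steps < max_steps):
        nxt = []
        for i, j, k in frontier:
            for dz, dy, dx in offsets:
                ni, nj, nk = i + dz, j + dy, k + dx
                if (
                    0 <= ni < shape[0]
                    and 0 <= nj < shape[1]
                    and 0 <= nk < shape[2]
                    and allowed[ni, nj, nk]
                    and not visited[ni, nj, nk]
                ):
                    visited[ni, nj, nk] = True
                    nxt.append((ni, nj, nk))
        frontier = nxt
        steps += 1
    return visited


def brute_components(mask: np.ndarray, connectivity: str = "all_neighbors"):
    """Connected components via repeated BFS; returns list of voxel-index sets."""
    remaining = mask.copy()
    comps = []
    while remaining.any():
        seed = np.zeros_like(remaining)
        seed[tuple(np.argwhere(remaining)[0])] = True
        comp = flood_fill(remaining, seed, connectivity=connectivity)
        comps.append({tuple(i) for i in np.argwhere(comp)})
        remaining &= ~comp
    return comps
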