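"""Spine-neck tracing: intensity-weighted shortest paths from head to dendrite.

The neck is the one-voxel-wide path from a voxel on the spine-head border to
the voxel preceding the first dendrite-border voxel.  Endpoints come from
the closest head-border/dendrite-border voxel pair under anisotropic
physical distance.  The path minimizes, over 26-connected steps, the cost

    step_length_µm * (1 + (I_max - I(v)) / (I_max - I_min))

so bright (neck-labeled) voxels are favored; I_max/I_min are taken over a
local corridor (bounding box of the endpoints padded 1 µm) to keep the
search tractable.  Heads touching the dendrite get no neck and are
classified stubby.  When necks are not visible in the image, a straight-line
head-centroid-to-dendrite distance stands in for spine length.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .detection import Voxel

logger = logging.getLogger(__name__)

CORRIDOR_PAD_UM = 1.0


@dataclass
class NeckPath:
    """An ordered voxel path from head border toward the dendrite.

    The last voxel is the one *preceding* the first dendrite-border voxel
    (dendrite voxels excluded).  ``length`` sums physical step lengths in µm.
    """

    voxels: list[Voxel]
    length: float
    mode: str = "traced"  # traced | straight_line
    label: int = 0


def border_voxels(mask: np.ndarray) -> np.ndarray:
    """(N, 3) indices of mask voxels with a 6-connected outside neighbor."""
    if not mask.any():
        raise ValueError("empty mask has no border")
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return np.argwhere(mask & ~eroded)


def closest_border_pair(
    head_mask: np.ndarray,
    dendrite_mask: np.ndarray,
    spacing: tuple[float, float, float],
) -> tuple[Voxel, Voxel, float]:
    """The (head-border voxel, dendrite-border voxel) pair at minimal
    anisotropic physical distance; ties break lexicographically on the head
    voxel, then the dendrite voxel."""
    dx, dy, dz = spacing
    sp = np.array([dz, dy, dx])
    hb = border_voxels(head_mask)
    db = border_voxels(dendrite_mask)
    tree = cKDTree((db + 0.5) * sp)
    dists, idx = tree.query((hb + 0.5) * sp)
    dmin = float(dists.min())
    # resolve ties deterministically: first head voxel (hb is lexicographic)
    # achieving dmin, then the lex-smallest dendrite voxel at that distance
    eps = 1e-9 * max(1.0, dmin)
    h_candidates = np.nonzero(dists <= dmin + eps)[0]
    hi = int(h_candidates[0])
    head_voxel = tuple(int(v) for v in hb[hi])
    near = tree.query_ball_point((hb[hi] + 0.5) * sp, dmin + eps)
    dend_voxel = tuple(int(v) for v in min(map(tuple, db[near])))
    return head_voxel, dend_voxel, dmin


_STEPS = [
    (di, dj, dk)
    for di, dj, dk in product((-1, 0, 1), repeat=3)
    if (di, dj, dk) != (0, 0, 0)
]


def trace_neck(
    image,
    head_voxel: Voxel,
    dendrite_voxel: Voxel,
    head_mask: np.ndarray,
    dendrite_mask: np.ndarray,
    label: int = 0,
) -> NeckPath:
    """Minimum-cost 26-connected path from the head border to the dendrite
    border, then truncated to the voxel preceding the dendrite.

    The path may not enter the head or dendrite interiors (the two endpoint
    voxels themselves are allowed).  Deterministic: cost ties resolve by
    lexicographic voxel order.  A fully dark corridor (no finite-cost path)
    falls back to straight-line mode with a warning.
    """
    data = np.asarray(image.data, dtype=float)
    sp = image.spacing_zyx
    start, goal = tuple(head_voxel), tuple(dendrite_voxel)

    pad = np.ceil(CORRIDOR_PAD_UM / sp).astype(int)
    lo = np.maximum(np.minimum(start, goal) - pad, 0)
    hi = np.minimum(np.maximum(start, goal) + pad + 1, data.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    corridor = data[sl]
    imax, imin = float(corridor.max()), float(corridor.min())
    span = imax - imin

    blocked = (head_mask | dendrite_mask)[sl].copy()
    lo_t = tuple(int(v) for v in lo)
    s_local = tuple(a - b for a, b in zip(start, lo_t))
    g_local = tuple(a - b for a, b in zip(goal, lo_t))
    blocked[s_local] = False
    blocked[g_local] = False

    def weight(local_voxel) -> float:
        if span == 0:
            return 1.0
        return 1.0 + (imax - corridor[local_voxel]) / span

    shape = corridor.shape
    dist: dict[tuple, float] = {s_local: 0.0}
    prev: dict[tuple, tuple] = {}
    heap: list[tuple[float, tuple]] = [(0.0, s_local)]
    found = False
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, np.inf):
            continue
        if u == g_local:
            found = True
            break
        for step in _STEPS:
            v = (u[0] + step[0], u[1] + step[1], u[2] + step[2])
            if not (0 <= v[0] < shape[0] and 0 <= v[1] < shape[1] and 0 <= v[2] < shape[2]):
                continue
            if blocked[v]:
                continue
            step_len = float(np.linalg.norm(np.asarray(step) * sp))
            nd = d + step_len * weight(v)
            if nd < dist.get(v, np.inf) - 1e-15:
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    if not found:
        logger.warning(
            "no finite-cost path from %s to %s; straight-line fallback", start, goal
        )
        length = float(np.linalg.norm((np.asarray(goal) - np.asarray(start)) * sp))
        return NeckPath(voxels=[], length=length, mode="straight_line", label=label)

    path_local = [g_local]
    while path_local[-1] != s_local:
        path_local.append(prev[path_local[-1]])
    path_local.reverse()
    path = [tuple(int(a + b) for a, b in zip(v, lo_t)) for v in path_local]
    path = path[:-1]  # drop the dendrite-border voxel itself
    length = _path_length(path, sp)
    return NeckPath(voxels=path, length=length, mode="traced", label=label)


def _path_length(path: list[Voxel], spacing_zyx: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    arr = np.asarray(path, dtype=float) * spacing_zyx
    return float(np.linalg.norm(np.diff(arr, axis=0), axis=1).sum())


def straight_line_length(
    head,
    dendrite_mask: np.ndarray,
    spacing: tuple[float, float, float],
) -> float:
    """Euclidean distance (µm) from the head centroid to the nearest
    dendrite-surface voxel center — the spine-length estimate used when
    necks are not resolvable in the image."""
    dx, dy, dz = spacing
    sp = np.array([dz, dy, dx])
    cx, cy, cz = head.centroid
    centroid_zyx = np.array([cz, cy, cx])
    db = border_voxels(dendrite_mask)
    return float(np.linalg.norm((db + 0.5) * sp - centroid_zyx, axis=1).min())


def classify_stubby(
    head_mask: np.ndarray,
    dendrite_mask: np.ndarray,
    connectivity: int = 26,
) -> str:
    """'stubby' iff any head voxel touches the dendrite mask (26-adjacency by
    default; pass connectivity=6 for strict face adjacency)."""
    structure = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    grown = ndimage.binary_dilation(head_mask, structure=structure)
    return "stubby" if bool((grown & dendrite_mask).any()) else "necked"


def retrace_neck(
    image,
    head_mask: np.ndarray,
    new_start_voxel: Voxel,
    dendrite_mask: np.ndarray,
    label: int = 0,
) -> NeckPath:
    """Re-trace with an imposed start on the head border; the dendrite
    endpoint is recomputed as the dendrite-border voxel nearest the new
    start (lexicographic tie-break)."""
    hb = border_voxels(head_mask)
    if not (hb == np.asarray(new_start_voxel)).all(axis=1).any():
        raise ValueError(f"{new_start_voxel} is not on the head border")
    sp = image.spacing_zyx
    db = border_voxels(dendrite_mask)
    d = np.linalg.norm((db - np.asarray(new_start_voxel)) * sp, axis=1)
    dmin = d.min()
    candidates = db[d <= dmin + 1e-9 * max(1.0, dmin)]
    dend_voxel = tuple(int(v) for v in min(map(tuple, candidates)))
    return trace_neck(image, tuple(new_start_voxel), dend_voxel, head_mask, dendrite_mask, label)
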