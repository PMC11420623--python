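"""Seeded 3D spine-head segmentation from the local intensity distribution.

Each seed grows into the connected set of voxels whose intensity exceeds a
per-seed threshold referenced to the local background:

    T = background + threshold_fraction * (seed_intensity - background)

with the background estimated as a low quantile of the intensities in a
one-voxel-thick spherical shell of radius ``radius_max`` around the seed.
The region is clipped to ``radius_max`` (physical µm) and to voxels outside
the dendrite mask.  Where two heads claim the same voxel, the voxel goes to
the head whose seed is physically nearer (watershed-style split), so a
double-seeded large head yields two adjacent, disjoint objects that can be
merged afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .detection import Seed, Voxel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable constants of the head-growing rule.

    threshold_fraction : fraction of the background-to-peak dynamic at which
        the region stops growing; higher values give smaller heads.
    radius_max : µm cap on head extent around its seed.
    connectivity : 6 or 26; voxel connectivity of the grown region.
    background_quantile : quantile of the shell intensities used as the
        local background estimate.
    """

    threshold_fraction: float = 0.5
    radius_max: float = 1.5
    connectivity: int = 26
    background_quantile: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.radius_max <= 0:
            raise ValueError("radius_max must be positive")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if not 0 <= self.background_quantile < 1:
            raise ValueError("background_quantile must be in [0, 1)")


@dataclass
class SpineHead:
    """One labeled 3D spine-head region grown from one or more seeds."""

    label: int
    voxels: np.ndarray  # (N, 3) int array of (i, j, k) indices
    seeds: list[Seed]
    spacing: tuple[float, float, float]
    provenance: str = "automatic"  # automatic | manual | merged
    touches_boundary: bool = False

    @property
    def centroid(self) -> np.ndarray:
        """Physical (x, y, z) µm coordinate of the voxel-center centroid."""
        dx, dy, dz = self.spacing
        mean_zyx = (self.voxels.mean(axis=0) + 0.5) * np.array([dz, dy, dx])
        return mean_zyx[::-1]

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)


def _ball_offsets(radius: float, spacing_zyx: np.ndarray):
    """Index offsets within physical radius of a voxel center, plus distances."""
    half = np.ceil(radius / spacing_zyx).astype(int)
    oi, oj, ok = np.meshgrid(
        *(np.arange(-h, h + 1) for h in half), indexing="ij"
    )
    d = np.sqrt(
        (oi * spacing_zyx[0]) ** 2
        + (oj * spacing_zyx[1]) ** 2
        + (ok * spacing_zyx[2]) ** 2
    )
    return oi, oj, ok, d


def local_threshold(image, seed: Seed, params: SegmentationParams) -> float:
    """Background-referenced threshold for one seed (see module docstring)."""
    return _threshold_and_background(image, seed, params)[0]


def _threshold_and_background(image, seed, params):
    data = np.asarray(image.data, dtype=float)
    sp = image.spacing_zyx
    oi, oj, ok, d = _ball_offsets(params.radius_max, sp)
    i, j, k = seed.voxel
    ii, jj, kk = oi + i, oj + j, ok + k
    inside = (
        (ii >= 0) & (ii < data.shape[0])
        & (jj >= 0) & (jj < data.shape[1])
        & (kk >= 0) & (kk < data.shape[2])
    )
    shell = (d <= params.radius_max) & (d > params.radius_max - float(sp.max())) & inside
    if shell.any():
        background = float(
            np.quantile(data[ii[shell], jj[shell], kk[shell]], params.background_quantile)
        )
    else:  # seed hugging the image boundary: fall back to the whole ball
        ball = (d <= params.radius_max) & inside
        background = float(
            np.quantile(data[ii[ball], jj[ball], kk[ball]], params.background_quantile)
        )
    background = min(background, seed.intensity)
    return (
        background + params.threshold_fraction * (seed.intensity - background),
        background,
    )


def segment_heads(
    image,
    seeds: list[Seed],
    dendrite_volume,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[list[SpineHead], np.ndarray]:
    """Grow every seed into a spine head; returns heads plus the label grid.

    Labels are assigned 1..n in seed order.  Seeds inside the dendrite mask
    are skipped with a warning.  Deterministic: identical inputs produce a
    byte-identical label grid.
    """
    data = np.asarray(image.data, dtype=float)
    dmask = dendrite_volume.mask
    if dmask.shape != data.shape:
        raise ValueError("image and dendrite grids are not aligned")
    sp = image.spacing_zyx
    structure = _structure(params.connectivity)

    label_grid = np.zeros(data.shape, dtype=np.int32)
    # nearest-seed ownership for contested voxels, tracked per voxel
    owner_dist = np.full(data.shape, np.inf)

    heads: list[SpineHead] = []
    regions: dict[int, np.ndarray] = {}
    kept_seeds: dict[int, Seed] = {}
    next_label = 0
    for seed in seeds:
        next_label += 1
        label = next_label
        if dmask[seed.voxel]:
            logger.warning("seed %s lies inside the dendrite mask; skipped", seed.voxel)
            next_label -= 1
            continue
        region = _grow_region(data, dmask, seed, params, sp, structure)
        regions[label] = region
        kept_seeds[label] = seed

    for label, region in regions.items():
        seed = kept_seeds[label]
        seed_pos = (np.asarray(seed.voxel) + 0.5) * sp
        vox = np.argwhere(region)
        dists = np.linalg.norm((vox + 0.5) * sp - seed_pos, axis=1)
        flat = np.ravel_multi_index(tuple(vox.T), data.shape)
        closer = dists < owner_dist.ravel()[flat]
        take = vox[closer]
        owner_flat = flat[closer]
        owner_dist.ravel()[owner_flat] = dists[closer]
        label_grid.ravel()[owner_flat] = label

    for label in regions:
        vox = np.argwhere(label_grid == label)
        if len(vox) == 0:  # fully usurped by a nearer seed; keep the seed voxel
            vox = np.array([kept_seeds[label].voxel])
            label_grid[tuple(vox[0])] = label
        touches = bool(
            (vox == 0).any()
            or (vox[:, 0] == data.shape[0] - 1).any()
            or (vox[:, 1] == data.shape[1] - 1).any()
            or (vox[:, 2] == data.shape[2] - 1).any()
        )
        if touches:
            logger.info("head %d touches the image boundary (truncated)", label)
        heads.append(
            SpineHead(
                label=label,
                voxels=vox,
                seeds=[kept_seeds[label]],
                spacing=image.spacing,
                provenance=kept_seeds[label].origin,
                touches_boundary=touches,
            )
        )
    return heads, label_grid


def _grow_region(
    data: np.ndarray,
    dendrite_mask: np.ndarray,
    seed: Seed,
    params: SegmentationParams,
    spacing_zyx: np.ndarray,
    structure: np.ndarray,
) -> np.ndarray:
    """Connected suprathreshold component containing the seed, within the
    radius cap and outside the dendrite.  Always contains the seed voxel."""

    class _View:
        # minimal stand-in so local_threshold can reuse the offsets helper
        def __init__(self, d, s):
            self.data, self.spacing_zyx = d, s

    threshold, background = _threshold_and_background(
        _View(data, spacing_zyx), seed, params
    )

    i, j, k = seed.voxel
    oi, oj, ok, d = _ball_offsets(params.radius_max, spacing_zyx)
    half = np.array(oi.shape) // 2
    lo = np.maximum(np.array(seed.voxel) - half, 0)
    hi = np.minimum(np.array(seed.voxel) + half + 1, data.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    crop = data[sl]
    dcrop = dendrite_mask[sl]
    # physical distance of each crop voxel from the seed
    off = tuple(
        np.arange(a, b) - c for (a, b), c in zip(zip(lo, hi), seed.voxel)
    )
    gi, gj, gk = np.meshgrid(*off, indexing="ij")
    dist = np.sqrt(
        (gi * spacing_zyx[0]) ** 2
        + (gj * spacing_zyx[1]) ** 2
        + (gk * spacing_zyx[2]) ** 2
    )
    if threshold > background:
        supra = crop >= threshold
    else:
        # zero-contrast seed (e.g. a background click): a flat plateau at
        # the background level must not flood the whole neighborhood
        supra = crop > background
    allowed = supra & (dist <= params.radius_max) & ~dcrop
    seed_local = tuple(np.asarray(seed.voxel) - lo)
    allowed[seed_local] = True  # region always contains its seed
    comp, _ = ndimage.label(allowed, structure=structure)
    region_crop = comp == comp[seed_local]
    region = np.zeros(data.shape, dtype=bool)
    region[sl] = region_crop
    return region


def merge_heads(
    label_grid: np.ndarray,
    heads: list[SpineHead],
    label_a: int,
    label_b: int,
) -> tuple[np.ndarray, list[SpineHead]]:
    """Merge head ``label_b`` into ``label_a``: one object with the union of
    voxels, provenance 'merged'.  Non-adjacent merges are permitted but
    logged."""
    by_label = {h.label: h for h in heads}
    for lab in (label_a, label_b):
        if lab not in by_label:
            raise KeyError(f"unknown head label {lab}")
    if label_a == label_b:
        raise ValueError("cannot merge a head with itself")
    a, b = by_label[label_a], by_label[label_b]

    grown = ndimage.binary_dilation(
        a.mask(label_grid.shape), structure=np.ones((3, 3, 3), bool)
    )
    if not grown[tuple(b.voxels.T)].any():
        logger.warning("merging non-adjacent heads %d and %d", label_a, label_b)

    out = label_grid.copy()
    out[out == label_b] = label_a
    merged = SpineHead(
        label=label_a,
        voxels=np.concatenate([a.voxels, b.voxels]),
        seeds=a.seeds + b.seeds,
        spacing=a.spacing,
        provenance="merged",
        touches_boundary=a.touches_boundary or b.touches_boundary,
    )
    new_heads = [merged if h.label == label_a else h for h in heads if h.label != label_b]
    return out, new_heads


def remove_head(
    label_grid: np.ndarray,
    heads: list[SpineHead],
    label: int,
) -> tuple[np.ndarray, list[SpineHead]]:
    """Clear one head's voxels; every other label is untouched."""
    if label not in {h.label for h in heads}:
        raise KeyError(f"unknown head label {label}")
    out = label_grid.copy()
    out[out == label] = 0
    return out, [h for h in heads if h.label != label]


def add_head_at(
    image,
    position: Voxel,
    dendrite_volume,
    params: SegmentationParams,
    label_grid: np.ndarray,
    heads: list[SpineHead],
    low_intensity_factor: float = 2.0,
) -> tuple[np.ndarray, list[SpineHead], SpineHead]:
    """Manually add a spine head by clicking inside it: derive a manual seed
    from the 5x5 window, grow it, and claim only voxels no existing head
    owns.  Background clicks produce a few-voxel object flagged in the log.
    """
    from .detection import add_seed_at

    if dendrite_volume.mask[position]:
        raise ValueError(f"position {position} lies inside the dendrite mask")
    seed = add_seed_at(image, position)
    data = np.asarray(image.data, dtype=float)
    region = _grow_region(
        data, dendrite_volume.mask, seed, params, image.spacing_zyx,
        _structure(params.connectivity),
    )
    region &= label_grid == 0
    region[seed.voxel] = label_grid[seed.voxel] == 0
    if not region.any():
        raise ValueError(f"position {position} is already claimed by another head")
    label = max((h.label for h in heads), default=0) + 1
    vox = np.argwhere(region)
    if len(vox) <= 3:
        logger.warning(
            "manual head %d at %s is tiny (%d voxels) — likely background",
            label, position, len(vox),
        )
    out = label_grid.copy()
    out[tuple(vox.T)] = label
    head = SpineHead(
        label=label,
        voxels=vox,
        seeds=[seed],
        spacing=image.spacing,
        provenance="manual",
    )
    return out, heads + [head], head
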