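"""Spine-head seed detection: 3D local maxima in a distance band.

Candidate spine heads are intensity maxima of the 26-neighborhood that lie
in a shell around the dendrite (``dist_min``..``dist_max`` µm from the
dendrite border), exceed an intensity floor, and survive a greedy
minimum-separation filter (brightest wins).  Manual seeds can be added at
arbitrary positions — exempt from all three criteria — and removed by
nearest-neighbor lookup, mirroring interactive editing in a headless,
coordinate-based form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

Voxel = tuple[int, int, int]  # (i, j, k) = (z, y, x) index


@dataclass(frozen=True)
class DetectionParams:
    """Constraints applied to automatic local maxima.

    intensity_min : ignore maxima dimmer than this (image intensity units);
        None selects an automatic floor of background + 0.5 x (peak -
        background), with the background taken as the image median.
    dist_min, dist_max : µm band around the dendrite border in which maxima
        are searched; excludes background blobs and spines of neighboring
        dendrites beyond the band.
    min_separation : µm imposed between retained maxima (greedy, brightest
        kept first); adapt to sparse vs dense spine distributions.
    smooth_sigma : optional Gaussian pre-smoothing in µm before maxima
        detection (local maxima are noise sensitive); 0 disables.
    """

    intensity_min: float | None = None
    dist_min: float = 0.0
    dist_max: float = 2.0
    min_separation: float = 0.3
    smooth_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.dist_min < self.dist_max:
            raise ValueError(
                f"need 0 <= dist_min < dist_max, got [{self.dist_min}, {self.dist_max}]"
            )
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


@dataclass(frozen=True)
class Seed:
    """A candidate spine-head maximum at ``voxel`` with the image value there."""

    voxel: Voxel
    intensity: float
    origin: str = "automatic"  # automatic | manual

    @property
    def position_zyx(self) -> np.ndarray:
        return np.asarray(self.voxel, dtype=float) + 0.5


def _physical_zyx(voxel, spacing_zyx: np.ndarray) -> np.ndarray:
    return (np.asarray(voxel, dtype=float) + 0.5) * spacing_zyx


def detect_local_maxima(
    image,
    border_distance: np.ndarray,
    params: DetectionParams,
    dendrite_mask: np.ndarray | None = None,
) -> list[Seed]:
    """Detect spine-head seeds around the dendrite.

    Returns strict-or-plateau 26-neighborhood maxima inside the distance
    band with intensity >= ``intensity_min``, separation-filtered, sorted by
    descending intensity.  A plateau contributes its lexicographically
    smallest voxel.  ``image`` is an :class:`~spinemorph.image_io.ImageStack`.
    """
    data = np.asarray(image.data, dtype=float)
    if border_distance.shape != data.shape:
        raise ValueError(
            f"distance field shape {border_distance.shape} != image {data.shape}"
        )
    if params.smooth_sigma > 0:
        data = ndimage.gaussian_filter(
            data, sigma=params.smooth_sigma / image.spacing_zyx
        )

    footprint = np.ones((3, 3, 3), dtype=bool)
    is_max = data >= ndimage.maximum_filter(data, footprint=footprint, mode="nearest")

    intensity_min = params.intensity_min
    if intensity_min is None:
        background = float(np.median(data))
        intensity_min = background + 0.5 * (float(data.max()) - background)

    in_band = (border_distance >= params.dist_min) & (
        border_distance <= params.dist_max
    )
    if dendrite_mask is not None:
        in_band &= ~dendrite_mask
    candidate = is_max & in_band & (data >= intensity_min)

    # adjacent candidate maxima are necessarily equal-valued plateaus;
    # keep one representative per plateau (lexicographically smallest voxel)
    labels, nlab = ndimage.label(candidate, structure=footprint)
    seeds: list[Seed] = []
    if nlab:
        idx = np.argwhere(candidate)  # argwhere is already lexicographic
        taken: set[int] = set()
        for i, j, k in idx:
            lab = int(labels[i, j, k])
            if lab in taken:
                continue
            taken.add(lab)
            seeds.append(Seed((int(i), int(j), int(k)), float(image.data[i, j, k])))

    seeds.sort(key=lambda s: (-s.intensity, s.voxel))
    return filter_by_separation(seeds, params.min_separation, image.spacing)


def filter_by_separation(
    seeds: list[Seed],
    min_separation: float,
    spacing: tuple[float, float, float],
) -> list[Seed]:
    """Greedy suppression: keep a seed iff it lies >= ``min_separation`` µm
    from every already-kept (brighter) seed.  ``seeds`` must be sorted by
    descending intensity."""
    if min_separation <= 0 or len(seeds) <= 1:
        return list(seeds)
    dx, dy, dz = spacing
    sp = np.array([dz, dy, dx])
    kept: list[Seed] = []
    kept_pos: list[np.ndarray] = []
    for seed in seeds:
        p = _physical_zyx(seed.voxel, sp)
        if all(np.linalg.norm(p - q) >= min_separation for q in kept_pos):
            kept.append(seed)
            kept_pos.append(p)
    return kept


def add_seed_at(image, position: Voxel, scan_slices: int = 0) -> Seed:
    """Create a manual seed at the brightest voxel of the in-plane 5x5 window
    centered on ``position`` (optionally scanning ``scan_slices`` slices above
    and below).  Manual seeds bypass the intensity, distance and separation
    criteria.  Plateau ties resolve to the lexicographically smallest voxel.
    """
    data = image.data
    i, j, k = position
    nz, ny, nx = data.shape
    if not (0 <= i < nz and 0 <= j < ny and 0 <= k < nx):
        raise ValueError(f"position {position} outside grid {data.shape}")
    i0, i1 = max(0, i - scan_slices), min(nz, i + scan_slices + 1)
    j0, j1 = max(0, j - 2), min(ny, j + 3)
    k0, k1 = max(0, k - 2), min(nx, k + 3)
    window = data[i0:i1, j0:j1, k0:k1]
    flat = int(np.argmax(window))  # argmax returns the first (lex-smallest) max
    di, dj, dk = np.unravel_index(flat, window.shape)
    voxel = (int(i0 + di), int(j0 + dj), int(k0 + dk))
    return Seed(voxel, float(data[voxel]), origin="manual")


def remove_nearest_seed(
    seeds: list[Seed],
    position: Voxel,
    spacing: tuple[float, float, float],
) -> tuple[list[Seed], Seed]:
    """Delete the seed physically nearest ``position``; returns the remaining
    list and the removed seed.  Ties resolve to the lexicographically
    smallest seed voxel."""
    if not seeds:
        raise ValueError("cannot remove from an empty seed list")
    dx, dy, dz = spacing
    sp = np.array([dz, dy, dx])
    p = _physical_zyx(position, sp)
    best = min(
        seeds,
        key=lambda s: (float(np.linalg.norm(_physical_zyx(s.voxel, sp) - p)), s.voxel),
    )
    return [s for s in seeds if s is not best], best
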