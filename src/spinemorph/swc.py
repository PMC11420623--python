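"""SWC dendrite models and their voxel realization.

An SWC file stores a neuron trace as a sequence of nodes, each a sphere
(x, y, z, radius, all in µm) linked to a parent node.  The dendrite shaft is
realized volumetrically by uniting the node spheres with conical frustums
along each parent-child segment, i.e. a tapered capsule whose radius is
interpolated linearly along the segment.  All geometry is computed in
physical units so anisotropic voxels (axial step larger than lateral) are
handled throughout.

Array convention: 3D grids are indexed ``[i, j, k]`` = ``[z, y, x]``; voxel
index ``(i, j, k)`` has its center at physical position
``((k + 0.5)·dx, (j + 0.5)·dy, (i + 0.5)·dz)`` relative to the grid origin.
User-facing spacing tuples are ``(dx, dy, dz)`` in µm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class SwcParseError(ValueError):
    """Raised when an SWC file violates the 7-column node-table contract."""


@dataclass(frozen=True)
class SwcNode:
    """One SWC node: a sphere of ``radius`` µm centered at (x, y, z) µm."""

    node_id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for a root

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class DendriteModel:
    """An ordered chain (or forest) of SWC nodes with parent->child edges."""

    nodes: list[SwcNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {n.node_id: n for n in self.nodes}

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: int) -> SwcNode:
        return self._by_id[node_id]

    @property
    def edges(self) -> list[tuple[SwcNode, SwcNode]]:
        """Parent->child node pairs."""
        return [
            (self._by_id[n.parent_id], n) for n in self.nodes if n.parent_id != -1
        ]

    def length(self) -> float:
        """Total dendrite length: sum of Euclidean parent-child segment lengths (µm)."""
        total = 0.0
        for parent, child in self.edges:
            total += float(np.linalg.norm(parent.position - child.position))
        return total

    def bounding_box(self, pad: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(min_xyz, max_xyz) in µm covering every node sphere.

        ``pad`` defaults to the maximum node radius, guaranteeing the box
        contains the full volumetric realization.
        """
        if not self.nodes:
            raise ValueError("empty model has no bounding box")
        pos = np.array([[n.x, n.y, n.z] for n in self.nodes])
        if pad is None:
            pad = max(n.radius for n in self.nodes)
        return pos.min(axis=0) - pad, pos.max(axis=0) + pad


def parse_swc(text: str) -> DendriteModel:
    """Parse whitespace-delimited 7-column SWC text ('#' lines are comments).

    Raises :class:`SwcParseError` naming the offending line for duplicate
    ids, dangling parents, non-positive radii or malformed rows.
    """
    nodes: list[SwcNode] = []
    seen: set[int] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            node = SwcNode(
                node_id=int(parts[0]),
                type_code=int(parts[1]),
                x=float(parts[2]),
                y=float(parts[3]),
                z=float(parts[4]),
                radius=float(parts[5]),
                parent_id=int(parts[6]),
            )
        except ValueError as exc:
            raise SwcParseError(f"line {lineno}: {exc}") from exc
        if node.node_id in seen:
            raise SwcParseError(f"line {lineno}: duplicate node id {node.node_id}")
        if node.radius <= 0:
            raise SwcParseError(f"line {lineno}: non-positive radius {node.radius}")
        if node.parent_id != -1 and node.parent_id not in seen:
            raise SwcParseError(
                f"line {lineno}: parent id {node.parent_id} not defined before use"
            )
        seen.add(node.node_id)
        nodes.append(node)
    return DendriteModel(nodes)


def write_swc(model: DendriteModel) -> str:
    """Serialize a model back to 7-column SWC text (round-trips exactly)."""
    buf = io.StringIO()
    buf.write("# id type x y z radius parent\n")
    for n in model.nodes:
        buf.write(
            f"{n.node_id} {n.type_code} {n.x:.6g} {n.y:.6g} {n.z:.6g} "
            f"{n.radius:.6g} {n.parent_id}\n"
        )
    return buf.getvalue()


def dendrite_length(model: DendriteModel) -> float:
    """Total traced length in µm (0 for empty or single-node models)."""
    return model.length()


@dataclass
class DendriteVolume:
    """Voxel realization of a dendrite plus a physical-unit border distance map.

    ``mask`` is True inside the dendrite.  ``border_distance`` holds, for every
    voxel outside the mask, the anisotropic Euclidean distance in µm to the
    nearest border voxel center; it is 0 on border voxels and inside the mask.
    The border is the set of inside voxels with at least one 6-connected
    outside neighbor.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]  # (dx, dy, dz) µm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # physical xyz of grid corner
    _border_distance: np.ndarray | None = None

    @property
    def spacing_zyx(self) -> np.ndarray:
        dx, dy, dz = self.spacing
        return np.array([dz, dy, dx], dtype=float)

    def border_mask(self) -> np.ndarray:
        """Inside voxels with a 6-connected outside neighbor (one-voxel shell)."""
        if not self.mask.any():
            raise ValueError("empty dendrite mask has no border")
        eroded = ndimage.binary_erosion(
            self.mask, structure=ndimage.generate_binary_structure(3, 1),
            border_value=0,
        )
        return self.mask & ~eroded

    @property
    def border_distance(self) -> np.ndarray:
        if self._border_distance is None:
            self._border_distance = border_distance_map(self)
        return self._border_distance


def rasterize_dendrite(
    model: DendriteModel,
    spacing: tuple[float, float, float],
    grid_shape: tuple[int, int, int] | None = None,
    origin: tuple[float, float, float] | None = None,
) -> DendriteVolume:
    """Rasterize the dendrite as node spheres united with tapered frustums.

    A voxel belongs to the dendrite iff its center lies within any node
    sphere or within the conical frustum joining a parent-child pair, the
    radius interpolated linearly by projected arclength (clamped to the
    segment, which also yields the spherical end caps).

    When ``grid_shape``/``origin`` are omitted they are derived from the
    model bounding box padded by the maximum node radius.
    """
    dx, dy, dz = spacing
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError(f"spacing components must be positive, got {spacing}")
    if not model.nodes:
        raise ValueError("cannot rasterize an empty model")

    sp = np.array([dx, dy, dz], dtype=float)
    if origin is None or grid_shape is None:
        lo, hi = model.bounding_box()
        lo = np.minimum(lo, 0.0) if origin is None else np.asarray(origin, float)
        if origin is None:
            origin = tuple(lo)
        if grid_shape is None:
            n_xyz = np.ceil((hi - np.asarray(origin)) / sp).astype(int) + 1
            grid_shape = (int(n_xyz[2]), int(n_xyz[1]), int(n_xyz[0]))
    org = np.asarray(origin, dtype=float)

    nz, ny, nx = grid_shape
    mask = np.zeros(grid_shape, dtype=bool)

    segments: list[tuple[np.ndarray, np.ndarray, float, float]] = []
    for n in model.nodes:
        # an isolated sphere is a degenerate segment
        segments.append((n.position, n.position, n.radius, n.radius))
    for parent, child in model.edges:
        segments.append((parent.position, child.position, parent.radius, child.radius))

    for p0, p1, r0, r1 in segments:
        rmax = max(r0, r1)
        lo_xyz = np.minimum(p0, p1) - rmax - org
        hi_xyz = np.maximum(p0, p1) + rmax - org
        k0, j0, i0 = [max(0, int(np.floor(lo_xyz[a] / sp[a]))) for a in (0, 1, 2)]
        k1 = min(nx - 1, int(np.ceil(hi_xyz[0] / sp[0])))
        j1 = min(ny - 1, int(np.ceil(hi_xyz[1] / sp[1])))
        i1 = min(nz - 1, int(np.ceil(hi_xyz[2] / sp[2])))
        if k1 < k0 or j1 < j0 or i1 < i0:
            continue
        ii, jj, kk = np.meshgrid(
            np.arange(i0, i1 + 1), np.arange(j0, j1 + 1), np.arange(k0, k1 + 1),
            indexing="ij",
        )
        centers = np.stack(
            [
                org[0] + (kk + 0.5) * sp[0],
                org[1] + (jj + 0.5) * sp[1],
                org[2] + (ii + 0.5) * sp[2],
            ],
            axis=-1,
        )
        axis = p1 - p0
        L2 = float(axis @ axis)
        rel = centers - p0
        if L2 == 0.0:
            t = np.zeros(centers.shape[:-1])
        else:
            t = np.clip(np.einsum("...c,c->...", rel, axis) / L2, 0.0, 1.0)
        nearest = p0 + t[..., None] * axis
        dist = np.linalg.norm(centers - nearest, axis=-1)
        rad = r0 + t * (r1 - r0)
        inside = dist <= rad
        mask[i0 : i1 + 1, j0 : j1 + 1, k0 : k1 + 1] |= inside

    return DendriteVolume(mask=mask, spacing=spacing, origin=tuple(org))


def border_distance_map(volume: DendriteVolume) -> np.ndarray:
    """Anisotropic Euclidean distance (µm) from every voxel to the dendrite border.

    Zero on border voxels and throughout the mask interior; strictly positive
    outside.  Distances are voxel-center to voxel-center with per-axis
    physical spacing, matching an exhaustive nearest-border-voxel search.
    """
    border = volume.border_mask()
    dist = ndimage.distance_transform_edt(~border, sampling=volume.spacing_zyx)
    dist[volume.mask] = 0.0
    return np.asarray(dist, dtype=float)
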