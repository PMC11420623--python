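"""Reading and writing calibrated intensity stacks and the result overlay.

Stacks are single-channel 3D TIFFs with voxel spacing in µm, read/written
via :mod:`tifffile` with ImageJ-style calibration tags honored (x/y
resolution tags plus the ImageJ ``spacing`` metadata for z).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A 3D single-channel intensity grid with per-axis voxel spacing.

    ``data`` is indexed ``[z, y, x]``; ``spacing`` is ``(dx, dy, dz)`` in µm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:  # 2D images are accepted as single-slice stacks
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D stack, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive: {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing_zyx(self) -> np.ndarray:
        dx, dy, dz = self.spacing
        return np.array([dz, dy, dx], dtype=float)

    @property
    def is_2d(self) -> bool:
        return self.data.shape[0] == 1

    def max_projection(self) -> np.ndarray:
        """Maximum-intensity projection along z (QC export only)."""
        return self.data.max(axis=0)


def read_stack(
    path: str | Path,
    spacing_override: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a single-channel 3D TIFF with its voxel calibration.

    Spacing comes from the TIFF/ImageJ metadata unless ``spacing_override``
    is given.  Multi-channel input or missing calibration without an
    override is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        if data.ndim == 4 or (data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:-1])):
            nchan = data.shape[-1] if data.ndim == 3 else data.shape[1]
            raise ValueError(
                f"{path.name}: expected a single-channel stack, got {nchan} channels"
            )
        spacing = spacing_override
        if spacing is None:
            spacing = _spacing_from_metadata(tf)
        if spacing is None:
            raise ValueError(
                f"{path.name}: no voxel calibration in metadata; pass spacing_override"
            )
    bit_depth = data.dtype.itemsize * 8
    return ImageStack(data=data, spacing=tuple(float(s) for s in spacing), bit_depth=bit_depth)


def _spacing_from_metadata(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (dx, dy, dz) µm from ImageJ tags, if present."""
    meta = tf.imagej_metadata
    if meta is None:
        return None
    dz = meta.get("spacing")
    page = tf.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if dz is None or xres is None or yres is None:
        return None
    xn, xd = xres.value
    yn, yd = yres.value
    if xn == 0 or yn == 0:
        return None
    return (xd / xn, yd / yn, float(dz))


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a calibrated single-channel TIFF (ImageJ-compatible tags)."""
    dx, dy, dz = stack.spacing
    tifffile.imwrite(
        path,
        stack.data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def write_overlay(
    image: ImageStack,
    dendrite_mask: np.ndarray,
    head_labels: np.ndarray,
    neck_paths: list,
    path: str | Path | None = None,
) -> np.ndarray:
    """Assemble the four-channel result overlay (CZYX).

    Channel 0 = original intensities, 1 = dendrite mask, 2 = spine-head
    labels, 3 = neck paths burned as one-voxel-wide rasters carrying their
    spine label.  Optionally written as a multi-channel ImageJ TIFF.
    """
    if dendrite_mask.shape != image.shape or head_labels.shape != image.shape:
        raise ValueError(
            f"layer shape mismatch: image {image.shape}, dendrite "
            f"{dendrite_mask.shape}, labels {head_labels.shape}"
        )
    neck_grid = np.zeros(image.shape, dtype=np.uint16)
    for neck in neck_paths:
        label = getattr(neck, "label", 1)
        for i, j, k in getattr(neck, "voxels", neck):
            neck_grid[i, j, k] = label
    overlay = np.stack(
        [
            image.data.astype(np.float32),
            dendrite_mask.astype(np.float32),
            head_labels.astype(np.float32),
            neck_grid.astype(np.float32),
        ]
    )
    if path is not None:
        dx, dy, dz = image.spacing
        tifffile.imwrite(
            path,
            overlay.transpose(1, 0, 2, 3),  # ImageJ hyperstacks are ZCYX
            imagej=True,
            resolution=(1.0 / dx, 1.0 / dy),
            metadata={"spacing": dz, "unit": "um", "axes": "ZCYX"},
        )
    return overlay
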