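"""Calibrated image stacks: containers, TIFF I/O, and physical-volume accounting.

A stack is a 2D or 3D intensity array plus a physical voxel size in
micrometres per axis. Axes follow the ``(z, y, x)`` convention for 3D data
and ``(y, x)`` for 2D. Voxel indices are 0-based, regions of interest are
half-open intervals, and the physical coordinate of a voxel is its centre,
so a straight run of ``n`` voxels spans ``(n - 1)`` inter-centre steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = ["ImageStack", "ROI", "read_stack", "write_stack", "stack_volume_mm3"]

UM3_PER_MM3 = 1e9


class CalibrationError(ValueError):
    """Raised when a file carries no voxel-size metadata and none is supplied."""


@dataclass
class ImageStack:
    """Intensity array with physical calibration.

    Parameters
    ----------
    voxels:
        2D ``(y, x)`` or 3D ``(z, y, x)`` intensity array.
    voxel_size:
        Micrometres per axis, same order and length as ``voxels.ndim``.
    channel:
        Free-text stain/channel label, e.g. ``"CD31"``.
    notes:
        Optional acquisition notes carried through to outputs.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, ...]
    channel: str = ""
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.voxels.ndim not in (2, 3):
            raise ValueError(f"expected 2D or 3D data, got {self.voxels.ndim}D")
        if len(self.voxel_size) != self.voxels.ndim:
            raise ValueError(
                f"voxel_size has {len(self.voxel_size)} entries "
                f"for {self.voxels.ndim}D data"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(
            np.isfinite(self.voxels)
        ):
            raise ValueError("intensity values must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def ndim(self) -> int:
        return self.voxels.ndim

    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel (µm³ for 3D, µm² for 2D)."""
        return float(np.prod(self.voxel_size))


@dataclass(frozen=True)
class ROI:
    """Axis-aligned region of interest as half-open voxel-index intervals."""

    bounds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if hi <= lo:
                raise ValueError(f"empty ROI interval [{lo}, {hi})")

    def validate_against(self, shape: Sequence[int]) -> None:
        if len(self.bounds) != len(shape):
            raise ValueError("ROI dimensionality does not match stack")
        for (lo, hi), n in zip(self.bounds, shape):
            if lo < 0 or hi > n:
                raise ValueError(f"ROI [{lo}, {hi}) outside axis of length {n}")

    def slices(self) -> tuple[slice, ...]:
        return tuple(slice(lo, hi) for lo, hi in self.bounds)

    def shape(self) -> tuple[int, ...]:
        return tuple(hi - lo for lo, hi in self.bounds)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as ImageJ-flavoured TIFF with voxel-size metadata.

    Calibration is stored in the standard ImageJ places: x/y in the TIFF
    resolution tags, z spacing in the ImageJ metadata, unit micron.
    """
    path = Path(path)
    vox = stack.voxels
    if vox.ndim == 3:
        dz, dy, dx = stack.voxel_size
        meta = {"spacing": dz, "unit": "um", "axes": "ZYX"}
    else:
        dy, dx = stack.voxel_size
        meta = {"unit": "um", "axes": "YX"}
    if stack.channel:
        meta["channel"] = stack.channel
    data = vox
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata=meta,
    )


def read_stack(
    path: str | Path,
    calibration_override: Sequence[float] | None = None,
    channel: str = "",
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack with its voxel calibration.

    Calibration is taken from file metadata (ImageJ or OME); an explicit
    ``calibration_override`` (µm per axis, ``(z, y, x)`` or ``(y, x)``)
    always wins. A file with no usable calibration and no override raises
    :class:`CalibrationError`.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_channel = ""
        voxel_size = None
        if calibration_override is not None:
            voxel_size = tuple(float(v) for v in calibration_override)
        else:
            voxel_size = _calibration_from_tiff(tif, data.ndim)
        ij = tif.imagej_metadata or {}
        meta_channel = str(ij.get("channel", "") or "")
    if voxel_size is None:
        raise CalibrationError(
            f"{path} carries no voxel-size metadata; pass calibration_override"
        )
    if len(voxel_size) != data.ndim:
        raise CalibrationError(
            f"calibration has {len(voxel_size)} entries for {data.ndim}D data"
        )
    return ImageStack(data, voxel_size, channel=channel or meta_channel)


def _calibration_from_tiff(tif: tifffile.TiffFile, ndim: int):
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is None or yres is None:
        return None
    # resolution tags with unit NONE and no ImageJ unit are tifffile filler,
    # not a real calibration
    unit_tag = page.tags.get("ResolutionUnit")
    ij_unit = (tif.imagej_metadata or {}).get("unit")
    if not ij_unit and (unit_tag is None or unit_tag.value == 1):
        return None

    def _per_px(tag):
        num, den = tag.value
        if num == 0:
            return None
        return den / num  # resolution is px per unit; invert

    dx = _per_px(xres)
    dy = _per_px(yres)
    if dx is None or dy is None:
        return None
    if ndim == 2:
        return (dy, dx)
    ij = tif.imagej_metadata or {}
    spacing = ij.get("spacing")
    if spacing is None:
        return None
    return (float(spacing), dy, dx)


def stack_volume_mm3(stack: ImageStack, roi: ROI | None = None) -> float:
    """Physical volume of a 3D stack (or ROI) in mm³.

    The product of voxel counts and voxel sizes gives µm³, converted at
    1 mm³ = 10⁹ µm³. For 2D stacks this is an area in mm².
    """
    shape = stack.shape
    if roi is not None:
        roi.validate_against(shape)
        shape = roi.shape()
    um = float(np.prod([n * s for n, s in zip(shape, stack.voxel_size)]))
    if stack.ndim == 3:
        return um / UM3_PER_MM3
    return um / 1e6  # µm² → mm²
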