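"""Trophoblast spheroid outgrowth quantification.

The motility readout is the total traced outgrowth area of an encapsulated
spheroid (body included), averaged over up to three manual traces, and the
per-spheroid fold change

    fold_change(day d) = (area_d - area_0) / area_0,

i.e. day-d outgrowth normalized to the same spheroid at encapsulation.
Manual masks are first-class inputs (matching the original traced
procedure); automatic thresholding is provided for phantom validation and
convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters

from .stacks import ImageStack

__all__ = [
    "SpheroidObservation",
    "FoldChangeResult",
    "outgrowth_area",
    "average_traces",
    "fold_change",
]


@dataclass(frozen=True)
class SpheroidObservation:
    spheroid_id: str
    day: int
    trace_areas_mm2: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be non-negative")
        if not (1 <= len(self.trace_areas_mm2) <= 3):
            raise ValueError("expect 1-3 traced areas")
        if any(a <= 0 for a in self.trace_areas_mm2):
            raise ValueError("areas must be positive")

    @property
    def mean_area_mm2(self) -> float:
        return float(np.mean(self.trace_areas_mm2))


@dataclass(frozen=True)
class FoldChangeResult:
    spheroid_id: str
    day: int
    fold_change: float


def outgrowth_area(
    image: ImageStack | np.ndarray,
    pixel_size_um: float | None = None,
    method: str = "threshold_auto",
    mask: np.ndarray | None = None,
    dark_object: bool = True,
) -> float:
    """Total outgrowth area in mm².

    ``manual_mask`` measures a provided boolean mask directly;
    ``threshold_auto`` Otsu-thresholds the image (``dark_object`` selects
    the below-threshold phase, the usual case for brightfield spheroids)
    and keeps the largest connected region, holes filled.
    """
    if isinstance(image, ImageStack):
        if pixel_size_um is None:
            pixel_size_um = image.voxel_size[-1]
        data = np.asarray(image.voxels, dtype=float)
    else:
        data = np.asarray(image, dtype=float)
        if pixel_size_um is None:
            raise ValueError("pixel size required for a bare array")
    px_area_mm2 = (pixel_size_um**2) / 1e6

    if method == "manual_mask":
        if mask is None:
            raise ValueError("manual_mask requires a mask")
        return float(np.asarray(mask, bool).sum()) * px_area_mm2
    if method != "threshold_auto":
        raise ValueError(f"unknown method {method!r}")

    if np.ptp(data) == 0:
        raise ValueError("constant image: no outgrowth detectable")
    t = filters.threshold_otsu(data)
    fg = data < t if dark_object else data > t
    if not fg.any():
        raise ValueError("no foreground detected")
    labels, n = ndimage.label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    region = ndimage.binary_fill_holes(labels == largest)
    return float(region.sum()) * px_area_mm2


def average_traces(areas_mm2) -> float:
    """Arithmetic mean of 1-3 replicate traced areas."""
    areas = list(areas_mm2)
    if not areas:
        raise ValueError("no traces supplied")
    if len(areas) > 3:
        raise ValueError("at most three traces per observation")
    if any(a <= 0 for a in areas):
        raise ValueError("areas must be positive")
    return float(np.mean(areas))


def fold_change(area_day_d: float, area_day0: float) -> float:
    """(area_d − area_0) / area_0; dimensionless, ≥ −1 for non-negative areas."""
    if area_day0 <= 0:
        raise ValueError("day-0 area must be positive")
    return (area_day_d - area_day0) / area_day0
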