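"""Threshold segmentation of SUV images into binary tumour subvolumes.

Relative mode keeps voxels at or above ``fraction * SUVmax(ROI)``; absolute
mode uses a fixed SUV cut (e.g. 2.5).  The threshold test is inclusive (>=),
applied at voxel centers inside the ROI, so a fraction of 1.0 returns exactly
the SUVmax voxel.  By default only the 26-connected component containing the
SUVmax voxel is kept, which models a single tumour focus and preserves the
nesting property mask(f1) ⊆ mask(f2) for f1 > f2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import BinaryMask
from .suv import EllipticalROI, SUVImage, suv_max_in_roi

# 3x3x3 structuring element: 26-connectivity
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class ThresholdSpec:
    """Segmentation rule: relative (%SUVmax) or absolute SUV threshold."""

    mode: str = "relative"  # {"relative", "absolute"}
    fraction: float | None = None
    absolute_suv: float | None = None
    keep_component_with_max: bool = True

    def __post_init__(self) -> None:
        if self.mode == "relative":
            if self.fraction is None or self.absolute_suv is not None:
                raise ValueError("relative mode requires fraction and no absolute_suv")
            if not 0 < self.fraction <= 1:
                raise ValueError(f"fraction must lie in (0, 1], got {self.fraction}")
        elif self.mode == "absolute":
            if self.absolute_suv is None or self.fraction is not None:
                raise ValueError("absolute mode requires absolute_suv and no fraction")
            if self.absolute_suv <= 0:
                raise ValueError(f"absolute_suv must be positive, got {self.absolute_suv}")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def relative(cls, fraction: float, keep_component_with_max: bool = True) -> "ThresholdSpec":
        return cls("relative", fraction=fraction, keep_component_with_max=keep_component_with_max)

    @classmethod
    def absolute(cls, suv: float, keep_component_with_max: bool = True) -> "ThresholdSpec":
        return cls("absolute", absolute_suv=suv, keep_component_with_max=keep_component_with_max)


def threshold_segment(img: SUVImage, roi: EllipticalROI, spec: ThresholdSpec) -> BinaryMask:
    """Segment the tumour subvolume at the requested threshold.

    Raises ``ValueError`` ("non-avid") when the ROI SUVmax is zero in relative
    mode, mirroring the exclusion of non-FDG-avid tumours.
    """
    vol = img.volume if isinstance(img, SUVImage) else img
    max_val, max_idx = suv_max_in_roi(img, roi)
    if spec.mode == "relative":
        if max_val <= 0:
            raise ValueError("non-avid: SUVmax within the ROI is zero")
        threshold = spec.fraction * max_val
    else:
        threshold = spec.absolute_suv

    inside = roi.contains_grid(vol)
    mask = inside & (vol.data >= threshold)

    if spec.keep_component_with_max and mask.any():
        labels, _ = ndimage.label(mask, structure=_CONN26)
        seed_label = labels[max_idx]
        if seed_label == 0:
            # absolute threshold above the ROI maximum: nothing to anchor on
            mask = np.zeros_like(mask)
        else:
            mask = labels == seed_label

    return BinaryMask.like(vol, mask)


def mask_volume_cc(mask: BinaryMask) -> float:
    """Volume of a binary mask in cm³ (voxel count × voxel volume)."""
    return mask.count * mask.voxel_volume_mm3 / 1000.0
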