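"""SUV quantification: activity→SUV conversion, SUVmax search, acquisition rules.

The standardized uptake value used throughout is the body-weight SUV,

    SUV(v) = activity(v) [Bq/ml] * body_weight [g] / injected_dose [Bq],

dimensionless under the 1 g/ml tissue-density convention.  SUVmax is the
single hottest voxel inside a user-drawn axis-aligned elliptical region of
interest — no SUVpeak averaging.  Tracer dosing follows the weight-based rule
of 4 MBq/kg capped at 600 MBq, and scan pairs enter the spatial analysis only
if they pass the eligibility screen in :func:`check_eligibility`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import ImageVolume, Vec3, _as_vec3

logger = logging.getLogger(__name__)

DOSE_MBQ_PER_KG = 4.0
DOSE_CAP_MBQ = 600.0
GLUCOSE_LIMIT_MMOL_L = 10.0


@dataclass
class AcquisitionMeta:
    """Injection and scan metadata needed for SUV scaling."""

    injected_dose_mbq: float
    body_weight_kg: float
    uptake_time_min: float = 90.0
    blood_glucose_mmol_l: float | None = None
    scan_role: str = "baseline"  # {"baseline", "post_crt"}

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0:
            raise ValueError(f"injected dose must be positive, got {self.injected_dose_mbq}")
        if self.body_weight_kg <= 0:
            raise ValueError(f"body weight must be positive, got {self.body_weight_kg}")
        if self.scan_role not in ("baseline", "post_crt"):
            raise ValueError(f"unknown scan role {self.scan_role!r}")


@dataclass(frozen=True)
class EllipticalROI:
    """Axis-aligned ellipsoid in world coordinates (mm).

    A voxel belongs to the ROI when its center satisfies
    sum(((x - center) / radii)**2) <= 1.
    """

    center: Vec3
    radii: Vec3

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _as_vec3(self.center))
        object.__setattr__(self, "radii", _as_vec3(self.radii))
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"ROI radii must be positive, got {self.radii}")

    def contains_grid(self, vol) -> np.ndarray:
        """Boolean array over ``vol``'s grid of voxel centers inside the ROI."""
        gx, gy, gz = vol.coord_grids()
        q = (
            ((gx - self.center[0]) / self.radii[0]) ** 2
            + ((gy - self.center[1]) / self.radii[1]) ** 2
            + ((gz - self.center[2]) / self.radii[2]) ** 2
        )
        return q <= 1.0


@dataclass(frozen=True, eq=False)
class SUVImage:
    """An :class:`ImageVolume` in SUV units with its acquisition provenance."""

    volume: ImageVolume
    meta: AcquisitionMeta | None = None

    def __post_init__(self) -> None:
        if np.any(self.volume.data < 0):
            raise ValueError("SUV images must be non-negative")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def shape(self):
        return self.volume.shape

    @property
    def spacing(self):
        return self.volume.spacing

    @property
    def origin(self):
        return self.volume.origin

    def coord_grids(self):
        return self.volume.coord_grids()


def to_suv(activity: ImageVolume, meta: AcquisitionMeta) -> SUVImage:
    """Convert an activity-concentration image (Bq/ml) to body-weight SUV.

    Negative input voxels (reconstruction artefacts) are clipped to zero and
    the clipped count is logged.
    """
    act = activity.data
    n_neg = int(np.count_nonzero(act < 0))
    if n_neg:
        logger.warning("to_suv: clipped %d negative activity voxels to 0", n_neg)
        act = np.clip(act, 0.0, None)
    weight_g = meta.body_weight_kg * 1000.0
    dose_bq = meta.injected_dose_mbq * 1e6
    suv = ImageVolume(act * weight_g / dose_bq, activity.spacing, activity.origin)
    return SUVImage(suv, meta)


def suv_max_in_roi(img: SUVImage | ImageVolume, roi: EllipticalROI) -> tuple[float, tuple[int, int, int]]:
    """Maximum SUV over ROI voxels and its voxel index.

    Ties are broken by the smallest linear (C-order) index.
    """
    vol = img.volume if isinstance(img, SUVImage) else img
    inside = roi.contains_grid(vol)
    if not inside.any():
        raise ValueError("ROI contains no voxel centers")
    vals = np.where(inside, vol.data, -np.inf)
    flat = int(np.argmax(vals))
    idx = np.unravel_index(flat, vol.shape)
    return float(vol.data[idx]), tuple(int(i) for i in idx)


def planned_dose_mbq(weight_kg: float) -> float:
    """Weight-based FDG dose: 4 MBq/kg, capped at 600 MBq."""
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    return min(DOSE_MBQ_PER_KG * weight_kg, DOSE_CAP_MBQ)


# ---------------------------------------------------------------------------
# Eligibility screen
# ---------------------------------------------------------------------------

EXCLUSION_ORDER = (
    "complete_metabolic_response",
    "non_avid",
    "missing_post_scan",
    "inseparable_uptake",
    "elevated_glucose",
)


@dataclass(frozen=True)
class EligibilityResult:
    included: bool
    reason: str | None = None


def check_eligibility(record) -> EligibilityResult:
    """Screen one patient record for the spatial-overlap analysis.

    Exclusion reasons are evaluated in a fixed order and the first match is
    reported: complete metabolic response, non-FDG-avid tumour, missing
    post-treatment scan, tumour uptake inseparable from normal tissue, and
    blood glucose at or above 10 mmol/L at either scan.
    """
    required = (
        "complete_metabolic_response",
        "fdg_avid",
        "has_post_scan",
        "uptake_separable",
        "glucose_baseline",
        "glucose_post",
    )
    for name in required:
        if getattr(record, name, None) is None:
            raise ValueError(f"missing eligibility flag: {name}")

    if record.complete_metabolic_response:
        return EligibilityResult(False, "complete_metabolic_response")
    if not record.fdg_avid:
        return EligibilityResult(False, "non_avid")
    if not record.has_post_scan:
        return EligibilityResult(False, "missing_post_scan")
    if not record.uptake_separable:
        return EligibilityResult(False, "inseparable_uptake")
    if (
        record.glucose_baseline >= GLUCOSE_LIMIT_MMOL_L
        or record.glucose_post >= GLUCOSE_LIMIT_MMOL_L
    ):
        return EligibilityResult(False, "elevated_glucose")
    return EligibilityResult(True)
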