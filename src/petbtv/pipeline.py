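"""End-to-end per-patient orchestration.

One patient run chains the stages: SUVmax within the ROI on each scan →
%SUVmax segmentation (40/50% baseline, 60–90% post-treatment) → propagation
of the post-treatment subvolumes to the planning grid through the
deformation field → volumes, overlap fractions and GTV coverage.  Errors
raised inside a stage are re-raised tagged with the stage name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import PatientRecord, filter_cohort, reproduce_tables  # noqa: F401  (re-exported surface)
from .grid import BinaryMask, DeformationField, ImageVolume
from .overlap import gtv_coverage, overlap_fraction
from .phantom import PhantomPair, PhantomSpec, generate_phantom_pair
from .register import warp_mask
from .segment import ThresholdSpec, mask_volume_cc, threshold_segment
from .suv import EllipticalROI, SUVImage, suv_max_in_roi


class PipelineError(RuntimeError):
    """Stage failure wrapper carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and ROIs for one patient run."""

    roi_pre: EllipticalROI
    roi_post: EllipticalROI
    pre_fractions: tuple[float, ...] = (0.4, 0.5)
    post_fractions: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6)
    keep_component_with_max: bool = True
    patient_id: int = 0

    def __post_init__(self) -> None:
        for f in (*self.pre_fractions, *self.post_fractions):
            if not 0 < f <= 1:
                raise ValueError(f"threshold fractions must lie in (0, 1], got {f}")


def _label(prefix: str, fraction: float) -> str:
    return f"{prefix}{round(fraction * 100)}%"


@dataclass(frozen=True, eq=False)
class PatientResult:
    """Everything a Table-1/Table-2 row needs, plus the masks themselves."""

    patient_id: int
    suv_max_pre: float
    suv_max_post: float
    pre_masks: dict          # label -> BinaryMask on the planning grid
    post_masks_native: dict  # label -> BinaryMask on the post-scan grid
    post_masks: dict         # label -> BinaryMask propagated to planning grid
    volumes_cc: dict         # label -> cm³ (post volumes after propagation)
    overlaps_pct: dict       # "Pre40|Post90" style keys -> percent
    gtv_coverage_pct: dict   # pre label -> percent of GTV covered

    def to_record(self) -> PatientRecord:
        return PatientRecord(
            patient_id=self.patient_id,
            suv_max_pre=self.suv_max_pre,
            suv_max_post=self.suv_max_post,
            volumes_cc=dict(self.volumes_cc),
            overlaps_pct=dict(self.overlaps_pct),
        )


def run_patient(
    pre_pet: SUVImage | ImageVolume,
    post_pet: SUVImage | ImageVolume,
    deformation: DeformationField,
    gtv: BinaryMask | None,
    config: RunConfig,
) -> PatientResult:
    """Run the full spatial-overlap analysis for one scan pair."""
    suv_pre, _ = _stage("suv", suv_max_in_roi, pre_pet, config.roi_pre)
    suv_post, _ = _stage("suv", suv_max_in_roi, post_pet, config.roi_post)

    pre_masks = {}
    for f in config.pre_fractions:
        spec = ThresholdSpec.relative(f, config.keep_component_with_max)
        pre_masks[_label("Pre", f)] = _stage(
            "segment", threshold_segment, pre_pet, config.roi_pre, spec
        )
    post_native = {}
    for f in config.post_fractions:
        spec = ThresholdSpec.relative(f, config.keep_component_with_max)
        post_native[_label("Post", f)] = _stage(
            "segment", threshold_segment, post_pet, config.roi_post, spec
        )

    post_masks = {
        label: _stage("register", warp_mask, mask, deformation)
        for label, mask in post_native.items()
    }

    volumes = {label: mask_volume_cc(m) for label, m in pre_masks.items()}
    volumes.update({label: mask_volume_cc(m) for label, m in post_masks.items()})
    if gtv is not None:
        volumes["GTV"] = mask_volume_cc(gtv)

    # a high-threshold post subvolume can be tiny (a voxel or two) and may
    # disappear under propagation; its overlap is then missing, not an error
    overlaps = {}
    for pre_label, pre_mask in pre_masks.items():
        for post_label, post_mask in post_masks.items():
            key = f"{pre_label.rstrip('%')}|{post_label.rstrip('%')}"
            if post_mask.count == 0:
                overlaps[key] = float("nan")
            else:
                overlaps[key] = _stage("overlap", overlap_fraction, pre_mask, post_mask)

    coverage = {}
    if gtv is not None:
        for pre_label, pre_mask in pre_masks.items():
            coverage[pre_label] = _stage("overlap", gtv_coverage, pre_mask, gtv)

    return PatientResult(
        patient_id=config.patient_id,
        suv_max_pre=suv_pre,
        suv_max_post=suv_post,
        pre_masks=pre_masks,
        post_masks_native=post_native,
        post_masks=post_masks,
        volumes_cc=volumes,
        overlaps_pct=overlaps,
        gtv_coverage_pct=coverage,
    )


def default_rois(spec: PhantomSpec) -> tuple[EllipticalROI, EllipticalROI]:
    """ROIs enclosing the phantom tumour on the baseline and post scans.

    The post ROI follows the ground-truth response map: the tumour ellipsoid
    maps to a shrunk copy displaced caudally, so a tumour-sized ROI centered
    on the displaced tumour center encloses all residual uptake.
    """
    center = spec.resolved_center()
    roi_pre = EllipticalROI(center, tuple(1.3 * r for r in spec.tumour_radii))
    post_center = list(center)
    post_center[spec.caudal_axis] += spec.caudal_shift
    roi_post = EllipticalROI(tuple(post_center), tuple(1.3 * r for r in spec.tumour_radii))
    return roi_pre, roi_post


def run_phantom_patient(
    spec: PhantomSpec,
    config: RunConfig | None = None,
    use_true_field: bool = True,
) -> tuple[PhantomPair, PatientResult]:
    """Generate a phantom and run the full analysis against it.

    With ``use_true_field=False`` the deformation step is skipped (identity
    field), which models analysing unregistered scans.
    """
    pair = generate_phantom_pair(spec)
    if config is None:
        roi_pre, roi_post = default_rois(spec)
        config = RunConfig(roi_pre=roi_pre, roi_post=roi_post, patient_id=spec.seed)
    deformation = (
        pair.field_true
        if use_true_field
        else DeformationField.identity(spec.grid_shape, spec.spacing)
    )
    result = run_patient(pair.pre_pet, pair.post_pet, deformation, pair.gtv_true, config)
    return pair, result
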