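"""SUV conversion, ROI maximum search, dosing and eligibility rules."""

import numpy as np
import pytest

from petbtv.cohort import PatientRecord
from petbtv.grid import ImageVolume
from petbtv.suv import (
    AcquisitionMeta,
    EllipticalROI,
    check_eligibility,
    planned_dose_mbq,
    suv_max_in_roi,
    to_suv,
)

from conftest import make_volume


class TestToSUV:
    def test_uniform_activity_forced_arithmetic(self):
        # 25 000 Bq/ml * 70 000 g / 3.5e8 Bq = 5.0
        act = make_volume(np.full((8, 8, 8), 25_000.0))
        meta = AcquisitionMeta(injected_dose_mbq=350.0, body_weight_kg=70.0)
        suv = to_suv(act, meta)
        assert np.allclose(suv.data, 5.0)

    def test_zero_activity_gives_zero_suv(self):
        suv = to_suv(make_volume(np.zeros((4, 4, 4))), AcquisitionMeta(300, 80))
        assert np.all(suv.data == 0)

    def test_matches_scalar_loop_oracle(self, rng):
        act = rng.uniform(0, 40_000, size=(9, 7, 6))
        meta = AcquisitionMeta(injected_dose_mbq=412.0, body_weight_kg=63.5)
        suv = to_suv(make_volume(act), meta)
        weight_g, dose_bq = 63.5 * 1000.0, 412.0 * 1e6
        oracle = np.empty_like(act)
        for i in range(act.shape[0]):
            for j in range(act.shape[1]):
                for k in range(act.shape[2]):
                    oracle[i, j, k] = act[i, j, k] * weight_g / dose_bq
        assert np.max(np.abs(suv.data - oracle)) == 0.0

    def test_negative_voxels_clipped(self):
        act = make_volume([[[-10.0, 20_000.0]]])
        suv = to_suv(act, AcquisitionMeta(400, 70))
        assert suv.data[0, 0, 0] == 0.0 and suv.data[0, 0, 1] > 0

    @pytest.mark.parametrize("scale", [0.5, 2.0, 7.3])
    def test_linear_in_activity_inverse_linear_in_dose(self, rng, scale):
        act = rng.uniform(0, 30_000, size=(6, 6, 6))
        base = to_suv(make_volume(act), AcquisitionMeta(400, 70)).data
        scaled_act = to_suv(make_volume(act * scale), AcquisitionMeta(400, 70)).data
        scaled_dose = to_suv(make_volume(act), AcquisitionMeta(400 * scale, 70)).data
        assert np.allclose(scaled_act, base * scale)
        assert np.allclose(scaled_dose, base / scale)

    @pytest.mark.parametrize("dose,weight", [(0, 70), (-5, 70), (400, 0), (400, -1)])
    def test_invalid_meta_rejected(self, dose, weight):
        with pytest.raises(ValueError):
            AcquisitionMeta(injected_dose_mbq=dose, body_weight_kg=weight)


class TestSUVMaxInROI:
    def test_uniform_image_lowest_linear_index(self):
        vol = make_volume(np.full((6, 6, 6), 3.6))
        roi = EllipticalROI(center=(5.0, 5.0, 5.0), radii=(20.0, 20.0, 20.0))
        val, idx = suv_max_in_roi(vol, roi)
        inside = roi.contains_grid(vol)
        first_inside = np.unravel_index(int(np.argmax(inside)), vol.shape)
        assert val == 3.6 and idx == tuple(int(i) for i in first_inside)

    def test_exhaustive_scan_oracle(self, rng):
        vol = make_volume(rng.uniform(0, 10, size=(12, 11, 10)))
        roi = EllipticalROI(center=(10.0, 9.0, 8.0), radii=(9.0, 7.0, 11.0))
        val, idx = suv_max_in_roi(vol, roi)
        best, best_idx = -np.inf, None
        for i in range(12):
            for j in range(11):
                for k in range(10):
                    x, y, z = i * 2.0, j * 2.0, k * 2.0
                    if ((x - 10) / 9) ** 2 + ((y - 9) / 7) ** 2 + ((z - 8) / 11) ** 2 <= 1:
                        if vol.data[i, j, k] > best:
                            best, best_idx = vol.data[i, j, k], (i, j, k)
        assert val == best and idx == best_idx

    def test_roi_covering_grid_equals_global_max(self, rng):
        vol = make_volume(rng.uniform(0, 10, size=(8, 8, 8)))
        roi = EllipticalROI(center=(7.0, 7.0, 7.0), radii=(100.0, 100.0, 100.0))
        val, _ = suv_max_in_roi(vol, roi)
        assert val == vol.data.max()

    def test_never_exceeds_global_max(self, rng):
        vol = make_volume(rng.uniform(0, 10, size=(10, 10, 10)))
        roi = EllipticalROI(center=(8.0, 8.0, 8.0), radii=(5.0, 4.0, 6.0))
        val, _ = suv_max_in_roi(vol, roi)
        assert val <= vol.data.max()

    def test_empty_roi_rejected(self):
        vol = make_volume(np.ones((8, 8, 8)))
        roi = EllipticalROI(center=(500.0, 500.0, 500.0), radii=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="no voxel"):
            suv_max_in_roi(vol, roi)


class TestPlannedDose:
    @pytest.mark.parametrize(
        "weight,expected", [(70.0, 280.0), (150.0, 600.0), (0.25, 1.0), (149.9, 599.6)]
    )
    def test_weight_rule_with_cap(self, weight, expected):
        assert planned_dose_mbq(weight) == pytest.approx(expected)

    def test_non_positive_weight_rejected(self):
        with pytest.raises(ValueError):
            planned_dose_mbq(0.0)


def _nominal_record(**overrides):
    rec = PatientRecord(
        patient_id=1,
        complete_metabolic_response=False,
        fdg_avid=True,
        has_post_scan=True,
        uptake_separable=True,
        glucose_baseline=5.5,
        glucose_post=5.0,
    )
    for k, v in overrides.items():
        setattr(rec, k, v)
    return rec


class TestEligibility:
    def test_nominal_record_included(self):
        assert check_eligibility(_nominal_record()).included

    @pytest.mark.parametrize(
        "overrides,reason",
        [
            ({"complete_metabolic_response": True}, "complete_metabolic_response"),
            ({"fdg_avid": False}, "non_avid"),
            ({"has_post_scan": False}, "missing_post_scan"),
            ({"uptake_separable": False}, "inseparable_uptake"),
            ({"glucose_baseline": 20.0, "glucose_post": 20.0}, "elevated_glucose"),
            ({"glucose_post": 10.0}, "elevated_glucose"),
        ],
    )
    def test_exclusion_reasons(self, overrides, reason):
        result = check_eligibility(_nominal_record(**overrides))
        assert not result.included and result.reason == reason

    def test_first_matching_reason_wins(self):
        rec = _nominal_record(complete_metabolic_response=True, fdg_avid=False)
        assert check_eligibility(rec).reason == "complete_metabolic_response"

    def test_missing_flag_named_in_error(self):
        rec = _nominal_record()
        rec.glucose_post = None
        with pytest.raises(ValueError, match="glucose_post"):
            check_eligibility(rec)
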