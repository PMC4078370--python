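"""Phantom generator: ground-truth geometry, PSF model, determinism."""

import numpy as np
import pytest

from petbtv.grid import ImageVolume
from petbtv.overlap import overlap_fraction
from petbtv.phantom import PhantomSpec, apply_psf_blur, generate_phantom_pair
from petbtv.register import invert_field, warp_mask
from petbtv.segment import ThresholdSpec, threshold_segment
from petbtv.suv import suv_max_in_roi
from petbtv.pipeline import default_rois


def _pre40_mask(pair):
    roi_pre, _ = default_rois(pair.spec)
    return threshold_segment(pair.pre_pet, roi_pre, ThresholdSpec.relative(0.4))


class TestGroundTruthGeometry:
    def test_full_containment_identity_case(self):
        spec = PhantomSpec(
            noise_sd=0.0, psf_fwhm=0.0, shrinkage=1.0, caudal_shift=0.0,
            containment_fraction=1.0,
        )
        pair = generate_phantom_pair(spec)
        assert overlap_fraction(_pre40_mask(pair), pair.residual_true) == 100.0

    def test_half_containment_voxel_count(self):
        spec = PhantomSpec(noise_sd=0.0, psf_fwhm=0.0, containment_fraction=0.5)
        pair = generate_phantom_pair(spec)
        pre40 = _pre40_mask(pair)
        inter = np.count_nonzero(pre40.data & pair.residual_true.data)
        frac = inter / pair.residual_true.count
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_requested_peak_suvs_recovered_without_psf(self):
        # patient-4-scale uptake values
        spec = PhantomSpec(
            noise_sd=0.0, psf_fwhm=0.0, baseline_peak_suv=10.6, post_peak_suv=5.7
        )
        pair = generate_phantom_pair(spec)
        roi_pre, roi_post = default_rois(spec)
        assert suv_max_in_roi(pair.pre_pet, roi_pre)[0] == pytest.approx(10.6)
        assert suv_max_in_roi(pair.post_pet, roi_post)[0] == pytest.approx(5.7)

    def test_gtv_is_single_connected_component(self, clean_pair):
        from scipy import ndimage

        _, n = ndimage.label(clean_pair.gtv_true.data, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_unreachable_containment_names_limiting_axis(self):
        spec = PhantomSpec(
            noise_sd=0.0, psf_fwhm=0.0,
            residual_radii=(25.0, 22.0, 18.0),  # as large as the tumour itself
            containment_fraction=1.0,
        )
        with pytest.raises(ValueError, match="axis"):
            generate_phantom_pair(spec)

    def test_post_peak_above_baseline_needs_explicit_flag(self):
        # models the paradoxical SUV rise seen in one cohort patient (4.0 -> 7.9)
        with pytest.raises(ValueError, match="allow_post_increase"):
            PhantomSpec(baseline_peak_suv=4.0, post_peak_suv=7.9).validate()
        spec = PhantomSpec(
            baseline_peak_suv=4.0, post_peak_suv=7.9, allow_post_increase=True,
            noise_sd=0.0, psf_fwhm=0.0,
        )
        pair = generate_phantom_pair(spec)
        _, roi_post = default_rois(spec)
        assert suv_max_in_roi(pair.post_pet, roi_post)[0] == pytest.approx(7.9)

    def test_field_round_trip_recovers_residual(self):
        spec = PhantomSpec(noise_sd=0.0, psf_fwhm=0.0, shrinkage=0.85, caudal_shift=8.0)
        pair = generate_phantom_pair(spec)
        fwd = warp_mask(pair.residual_true, pair.field_true)
        back = warp_mask(fwd, invert_field(pair.field_true))
        inter = np.count_nonzero(back.data & pair.residual_true.data)
        dice = 2 * inter / (back.count + pair.residual_true.count)
        assert dice >= 0.99


class TestDeterminism:
    def test_identical_spec_and_seed_bit_identical(self):
        spec = PhantomSpec(seed=42)
        a, b = generate_phantom_pair(spec), generate_phantom_pair(spec)
        assert np.array_equal(a.pre_pet.data, b.pre_pet.data)
        assert np.array_equal(a.post_pet.data, b.post_pet.data)
        assert np.array_equal(a.residual_true.data, b.residual_true.data)
        assert np.array_equal(a.field_true.displacement, b.field_true.displacement)

    def test_different_seed_different_noise(self):
        a = generate_phantom_pair(PhantomSpec(seed=1))
        b = generate_phantom_pair(PhantomSpec(seed=2))
        assert not np.array_equal(a.pre_pet.data, b.pre_pet.data)


class TestPSFModel:
    def test_zero_fwhm_is_identity(self, rng):
        img = ImageVolume(rng.uniform(0, 5, (10, 10, 10)), (2.0, 2.0, 2.0))
        out = apply_psf_blur(img, 0.0)
        assert out is img

    def test_interior_spike_peak_drops_sum_conserved(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1000.0
        img = ImageVolume(data, (2.0, 2.0, 2.0))
        out = apply_psf_blur(img, 4.0)  # fwhm = 2 x spacing
        assert out.data.max() < 1000.0
        assert out.data.sum() == pytest.approx(1000.0, rel=1e-6)

    def test_gaussian_semigroup(self):
        rng = np.random.default_rng(3)
        from scipy import ndimage

        img = ImageVolume(
            ndimage.gaussian_filter(rng.uniform(0, 10, (24, 24, 24)), 1.0),
            (2.0, 2.0, 2.0),
        )
        a, b = 5.0, 7.0
        twice = apply_psf_blur(apply_psf_blur(img, a), b)
        once = apply_psf_blur(img, np.hypot(a, b))
        assert np.max(np.abs(twice.data - once.data)) < 1e-3 * img.data.max()

    def test_recovery_coefficient_monotone_in_fwhm(self):
        # small residual volumes read lower as scanner resolution worsens
        maxima = []
        for fwhm in (0.0, 2.0, 4.0, 6.0, 8.0):
            spec = PhantomSpec(noise_sd=0.0, psf_fwhm=fwhm)
            pair = generate_phantom_pair(spec)
            _, roi_post = default_rois(spec)
            maxima.append(suv_max_in_roi(pair.post_pet, roi_post)[0])
        assert all(m1 >= m2 for m1, m2 in zip(maxima, maxima[1:]))

    def test_negative_fwhm_rejected(self, rng):
        img = ImageVolume(rng.uniform(0, 5, (6, 6, 6)), (2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            apply_psf_blur(img, -1.0)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(spacing=(0.0, 2.0, 2.0)),
            dict(residual_radii=(30.0, 9.0, 8.0)),
            dict(containment_fraction=1.5),
            dict(shrinkage=0.0),
            dict(noise_sd=-0.1),
            dict(background_suv=5.0),  # >= 40% of the baseline peak
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs).validate()
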