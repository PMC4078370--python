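"""Paired pre/post-chemoradiotherapy PET+CT phantoms with known ground truth.

Each phantom emulates the measurement situation of a baseline and a ~6-week
post-CRT FDG-PET of a pancreatic tumour, on a shared planning grid:

* baseline uptake: a truncated 3D Gaussian profile inside an ellipsoidal
  gross tumour volume (GTV), scaled so the hottest voxel equals the requested
  baseline peak SUV over a uniform background;
* residual post-CRT uptake: a smaller truncated-Gaussian hot region whose
  voxel-counted containment inside the baseline 40%-of-peak region is a
  controlled parameter (the residual center is moved outward from the
  baseline peak along the first grid axis, solved by bisection);
* treatment response geometry: uniform shrinkage about the tumour center
  composed with a caudal translation (third grid axis, increasing index =
  inferior, configurable), returned exactly as the ground-truth deformation
  field in the pull-back convention;
* measurement physics: isotropic Gaussian point-spread blur (the source of
  the recovery-coefficient effect — small hot volumes read low) and additive
  Gaussian voxel noise in SUV units, seeded.

Sinogram-level simulation, attenuation and respiratory motion are out of
scope: the pipeline operates on reconstructed SUV images.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import (
    BinaryMask,
    DeformationField,
    ImageVolume,
    Vec3,
    save_field,
    save_image,
    save_mask,
)

# FWHM = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493
# tumour/residual ellipsoid semi-axis expressed in profile sigmas
RADIUS_IN_SIGMA = 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth parameters of one synthetic patient.

    Defaults are cohort-scale conditions: a ~41.5 cm³ GTV, baseline peak
    SUV 8.0 and post-CRT peak 3.6 (cohort medians), a ~3 cm³ residual hot
    region 80% contained in the baseline 40% region, 0.8 linear shrinkage
    with a 10 mm caudal shift, 6 mm PET resolution and 0.2 SUV noise.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: Vec3 = (2.0, 2.0, 2.0)
    tumour_center: Vec3 | None = None  # default: grid center (mm)
    tumour_radii: Vec3 = (25.0, 22.0, 18.0)
    background_suv: float = 1.0
    baseline_peak_suv: float = 8.0
    post_peak_suv: float = 3.6
    residual_radii: Vec3 = (10.0, 9.0, 8.0)
    containment_fraction: float = 0.8
    shrinkage: float = 0.8
    caudal_shift: float = 10.0
    psf_fwhm: float = 6.0
    noise_sd: float = 0.2
    seed: int = 0
    caudal_axis: int = 2
    allow_post_increase: bool = False

    def resolved_center(self) -> tuple[float, ...]:
        if self.tumour_center is not None:
            return tuple(float(c) for c in self.tumour_center)
        return tuple((n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing))

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(r <= 0 for r in self.tumour_radii) or any(r <= 0 for r in self.residual_radii):
            raise ValueError("ellipsoid radii must be positive")
        if any(rr > tr for rr, tr in zip(self.residual_radii, self.tumour_radii)):
            raise ValueError(
                f"residual_radii {self.residual_radii} must not exceed "
                f"tumour_radii {self.tumour_radii} on any axis"
            )
        if self.post_peak_suv > self.baseline_peak_suv and not self.allow_post_increase:
            raise ValueError(
                "post_peak_suv exceeds baseline_peak_suv; set allow_post_increase "
                "to model a paradoxical SUV rise"
            )
        if not 0.0 <= self.containment_fraction <= 1.0:
            raise ValueError(f"containment_fraction must lie in [0, 1], got {self.containment_fraction}")
        if not 0.0 < self.shrinkage <= 1.0:
            raise ValueError(f"shrinkage must lie in (0, 1], got {self.shrinkage}")
        if self.psf_fwhm < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm and noise_sd must be non-negative")
        if self.background_suv < 0:
            raise ValueError("background_suv must be non-negative")
        if self.background_suv >= 0.4 * self.baseline_peak_suv:
            raise ValueError(
                "background_suv must stay below 40% of the baseline peak, "
                "otherwise the baseline 40% region is unbounded"
            )
        if self.caudal_axis not in (0, 1, 2):
            raise ValueError(f"caudal_axis must be 0, 1 or 2, got {self.caudal_axis}")


@dataclass(frozen=True, eq=False)
class PhantomPair:
    """One synthetic patient: images, ground-truth masks and field."""

    pre_pet: ImageVolume
    post_pet: ImageVolume
    pre_ct: ImageVolume
    post_ct: ImageVolume
    gtv_true: BinaryMask
    residual_true: BinaryMask
    field_true: DeformationField
    spec: PhantomSpec
    residual_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    achieved_containment: float = 1.0


def apply_psf_blur(img: ImageVolume, fwhm_mm: float) -> ImageVolume:
    """Model scanner resolution: Gaussian blur with the given FWHM in mm.

    A FWHM of 0 returns the input unchanged.  The kernel is normalized, so
    total activity is conserved away from the volume boundary (reflective
    handling at the edges).
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return img
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in img.spacing]
    blurred = ndimage.gaussian_filter(img.data, sigma=sigma_vox, mode="reflect")
    return ImageVolume(blurred, img.spacing, img.origin)


def _ellipsoid_mask(grids, center, radii) -> np.ndarray:
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def _gaussian_profile(grids, center, sigmas) -> np.ndarray:
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, sigmas))
    return np.exp(-0.5 * q)


def _truncated_blob(grids, center, radii, background, peak) -> tuple[np.ndarray, np.ndarray]:
    """Background plus a truncated Gaussian blob whose max voxel equals peak."""
    sigmas = [r / RADIUS_IN_SIGMA for r in radii]
    support = _ellipsoid_mask(grids, center, radii)
    if not support.any():
        raise ValueError("blob support contains no voxel centers")
    g = _gaussian_profile(grids, center, sigmas)
    g_max = g[support].max()
    img = np.full(support.shape, float(background))
    img[support] += (peak - background) * g[support] / g_max
    return img, support


def _containment_of(res_mask: np.ndarray, pre40: np.ndarray) -> float:
    n = int(res_mask.sum())
    if n == 0:
        raise ValueError("residual region contains no voxel centers")
    return int((res_mask & pre40).sum()) / n


def _solve_residual_center(spec: PhantomSpec, grids, center, pre40: np.ndarray) -> tuple[float, ...]:
    """Place the residual ellipsoid center to hit the requested containment.

    The center moves outward from the baseline peak along the first grid
    axis; the voxel-counted containment in the baseline 40% region is
    monotone non-increasing in the offset, so bisection applies.
    """
    rho = spec.containment_fraction
    r_res = spec.residual_radii

    def mask_at(u: float) -> np.ndarray:
        c = (center[0] + u, center[1], center[2])
        return _ellipsoid_mask(grids, c, r_res)

    f0 = _containment_of(mask_at(0.0), pre40)
    if rho > f0 + 1e-9:
        # concentric placement is the best case; name the axis blocking it
        thr_frac = (0.4 * spec.baseline_peak_suv - spec.background_suv) / (
            spec.baseline_peak_suv - spec.background_suv
        )
        a40 = [
            (r / RADIUS_IN_SIGMA) * np.sqrt(max(-2.0 * np.log(thr_frac), 0.0))
            for r in spec.tumour_radii
        ]
        ratios = [rr / a for rr, a in zip(r_res, a40)]
        axis = int(np.argmax(ratios))
        raise ValueError(
            f"containment_fraction {rho} unreachable: residual radius "
            f"{r_res[axis]} mm exceeds the baseline 40% region semi-axis "
            f"{a40[axis]:.1f} mm on axis {axis} (best achievable {f0:.3f})"
        )
    if rho >= f0 - 1e-12:
        return (center[0], center[1], center[2])

    # upper bracket: residual fully outside the 40% region along axis 0
    pre40_idx = np.nonzero(pre40)
    x_coords = grids[0].ravel()
    hi = float(x_coords[pre40_idx[0].max()] - center[0] + r_res[0] + 2.0 * spec.spacing[0])
    grid_max_x = x_coords[-1]
    if center[0] + hi + r_res[0] > grid_max_x:
        raise ValueError(
            "grid too small to place the residual region at the requested "
            "containment_fraction; enlarge grid_shape along axis 0"
        )
    lo, f_lo = 0.0, f0
    f_hi = _containment_of(mask_at(hi), pre40)
    for _ in range(60):
        if hi - lo <= 0.005:
            break
        mid = 0.5 * (lo + hi)
        f_mid = _containment_of(mask_at(mid), pre40)
        if f_mid >= rho:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    u = hi if abs(f_hi - rho) <= abs(f_lo - rho) else lo
    return (center[0] + u, center[1], center[2])


def generate_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate one paired pre/post-CRT phantom with exact ground truth.

    The clean (noise- and blur-free) baseline and post images are built
    analytically; the post image is evaluated through the inverse of the
    ground-truth response map (shrinkage about the tumour center plus caudal
    translation), then blurred by the PSF and perturbed by seeded Gaussian
    noise.  The returned deformation field maps planning-grid points into the
    post scan (pull-back), so warping post-scan masks through it places them
    on the planning grid.
    """
    spec.validate()
    shape, spacing = spec.grid_shape, spec.spacing
    center = spec.resolved_center()
    template = ImageVolume(np.zeros(shape), spacing)
    grids = template.coord_grids()

    # --- baseline PET -------------------------------------------------------
    pre_clean, gtv = _truncated_blob(
        grids, center, spec.tumour_radii, spec.background_suv, spec.baseline_peak_suv
    )
    pre40_true = pre_clean >= 0.4 * spec.baseline_peak_suv

    # --- residual placement on the planning grid ---------------------------
    res_center = _solve_residual_center(spec, grids, center, pre40_true)
    residual_true = _ellipsoid_mask(grids, res_center, spec.residual_radii)
    achieved = _containment_of(residual_true, pre40_true)

    # --- ground-truth response map and field --------------------------------
    s = spec.shrinkage
    t_vec = np.zeros(3)
    t_vec[spec.caudal_axis] = spec.caudal_shift
    disp = np.empty((*shape, 3))
    for a in range(3):
        disp[..., a] = (s - 1.0) * (grids[a] - center[a]) + t_vec[a]
    field_true = DeformationField(disp, spacing)

    # --- post-CRT PET: residual blob seen through the response map ----------
    # T(x) = c + s*(x - c) + t ; post(y) = blob(T^{-1}(y))
    inv_grids = tuple((g - center[a] - t_vec[a]) / s + center[a] for a, g in enumerate(grids))
    post_clean, _ = _truncated_blob(
        inv_grids, res_center, spec.residual_radii, spec.background_suv, spec.post_peak_suv
    )

    # --- CT companions (texture for alignment, tumour contrast) -------------
    body_radii = tuple(0.45 * (n - 1) * sp for n, sp in zip(shape, spacing))
    body = _ellipsoid_mask(grids, center, body_radii)
    texture = (
        8.0 * np.sin(grids[0] / 17.0) * np.sin(grids[1] / 23.0)
        + 5.0 * np.sin(grids[2] / 19.0)
    )
    pre_ct_data = np.where(body, 40.0 + texture, -1000.0)
    pre_ct_data[gtv] += 30.0
    gtv_post = _ellipsoid_mask(inv_grids, center, spec.tumour_radii)
    post_ct_data = np.where(body, 40.0 + texture, -1000.0)
    post_ct_data[gtv_post] += 30.0

    # --- measurement physics -------------------------------------------------
    rng = np.random.default_rng(spec.seed)
    pre_img = apply_psf_blur(ImageVolume(pre_clean, spacing), spec.psf_fwhm)
    post_img = apply_psf_blur(ImageVolume(post_clean, spacing), spec.psf_fwhm)
    pre_data, post_data = pre_img.data, post_img.data
    if spec.noise_sd > 0:
        pre_data = pre_data + rng.normal(0.0, spec.noise_sd, shape)
        post_data = post_data + rng.normal(0.0, spec.noise_sd, shape)
    pre_data = np.clip(pre_data, 0.0, None)
    post_data = np.clip(post_data, 0.0, None)

    return PhantomPair(
        pre_pet=ImageVolume(pre_data, spacing),
        post_pet=ImageVolume(post_data, spacing),
        pre_ct=ImageVolume(pre_ct_data, spacing),
        post_ct=ImageVolume(post_ct_data, spacing),
        gtv_true=BinaryMask(gtv, spacing),
        residual_true=BinaryMask(residual_true, spacing),
        field_true=field_true,
        spec=spec,
        residual_center=tuple(float(c) for c in res_center),
        achieved_containment=float(achieved),
    )


def write_phantom_pair(pair: PhantomPair, outdir: str | Path) -> None:
    """Write a phantom pair as NIfTI volumes plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_image(pair.pre_pet, outdir / "pre_pet.nii.gz")
    save_image(pair.post_pet, outdir / "post_pet.nii.gz")
    save_image(pair.pre_ct, outdir / "pre_ct.nii.gz")
    save_image(pair.post_ct, outdir / "post_ct.nii.gz")
    save_mask(pair.gtv_true, outdir / "gtv_true.nii.gz")
    save_mask(pair.residual_true, outdir / "residual_true.nii.gz")
    save_field(pair.field_true, outdir / "field_true.nii.gz")
    spec_dict = asdict(pair.spec)
    sidecar = {
        "spec": spec_dict,
        "seed": pair.spec.seed,
        "true_pre_peak_suv": pair.spec.baseline_peak_suv,
        "true_post_peak_suv": pair.spec.post_peak_suv,
        "residual_center_mm": list(pair.residual_center),
        "achieved_containment": pair.achieved_containment,
    }
    (outdir / "phantom.json").write_text(json.dumps(sidecar, indent=2))
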