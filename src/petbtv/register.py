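"""Alignment and contour propagation through dense deformation fields.

The non-rigid registration optimizer itself is out of scope: the pipeline
consumes a verified deformation field (known exactly on phantoms) and only
implements (i) a deterministic translation-only rigid alignment as the coarse
pre-alignment step, (ii) propagation of binary masks through a field, and
(iii) field quality validation (Jacobian/folding report).

Fields use the pull-back convention: a fixed-grid point x samples the moving
image at x + d(x).  Propagating a contour drawn on the moving (post-CRT) scan
onto the fixed (planning) grid is therefore a single resampling of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, DeformationField, ImageVolume, Vec3, _as_vec3


@dataclass(frozen=True)
class RigidTransform:
    """Pure translation (mm); rotation fixed at identity."""

    translation: Vec3

    def __post_init__(self) -> None:
        object.__setattr__(self, "translation", _as_vec3(self.translation))
        if not np.all(np.isfinite(self.translation)):
            raise ValueError(f"non-finite translation {self.translation}")


@dataclass(frozen=True)
class FieldReport:
    min_jacobian: float
    max_jacobian: float
    max_displacement_mm: float
    folding_fraction: float

    @property
    def ok(self) -> bool:
        return self.min_jacobian > 0


# ---------------------------------------------------------------------------
# Rigid translation search
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return -np.inf
    return float((a * b).sum() / denom)


def _ncc_at_voxel_shift(fixed: np.ndarray, moving: np.ndarray, shift) -> float:
    """NCC under the pull-back pairing fixed(x) vs moving(x + shift).

    Integer voxel shift; the score is computed on the overlap region without
    interpolation.
    """
    f_sl, m_sl = [], []
    for n, s in zip(fixed.shape, shift):
        if abs(s) >= n:
            return -np.inf
        if s >= 0:
            f_sl.append(slice(0, n - s))
            m_sl.append(slice(s, n))
        else:
            f_sl.append(slice(-s, n))
            m_sl.append(slice(0, n + s))
    return _ncc(fixed[tuple(f_sl)], moving[tuple(m_sl)])


def _better(cand, best) -> bool:
    """Deterministic ordering: higher score, then smaller norm, then lexicographic."""
    c_score, c_shift = cand
    b_score, b_shift = best
    if c_score > b_score + 1e-12:
        return True
    if c_score < b_score - 1e-12:
        return False
    c_key = (float(np.dot(c_shift, c_shift)), tuple(c_shift))
    b_key = (float(np.dot(b_shift, b_shift)), tuple(b_shift))
    return c_key < b_key


def rigid_align(
    moving: ImageVolume,
    fixed: ImageVolume,
    search_mm: float = 20.0,
    subvoxel: bool = True,
) -> RigidTransform:
    """Translation maximizing normalized cross-correlation, coarse to fine.

    An exhaustive integer-voxel grid search on a 2x-decimated pyramid level is
    refined at full resolution, then (optionally) by a sub-voxel grid search
    at 1/2 and 1/4 voxel steps using trilinear interpolation.  Deterministic:
    score ties resolve to the smallest translation norm, then lexicographic
    order.  The returned translation maps fixed-grid points into the moving
    image, i.e. moving sampled at x + t matches fixed at x.
    """
    f, m = fixed.data, moving.data
    if fixed.shape != moving.shape or not np.allclose(fixed.spacing, moving.spacing):
        raise ValueError("rigid_align expects images on congruent grids")
    if np.ptp(f) == 0 or np.ptp(m) == 0:
        raise ValueError("cannot align constant images")
    spacing = np.asarray(fixed.spacing)
    max_vox = np.maximum(1, np.ceil(search_mm / spacing).astype(int))

    # coarse level: decimate by 2
    fc, mc = f[::2, ::2, ::2], m[::2, ::2, ::2]
    max_c = np.maximum(1, max_vox // 2)
    best = (-np.inf, np.zeros(3, dtype=int))
    for i in range(-max_c[0], max_c[0] + 1):
        for j in range(-max_c[1], max_c[1] + 1):
            for k in range(-max_c[2], max_c[2] + 1):
                shift = np.array([i, j, k])
                cand = (_ncc_at_voxel_shift(fc, mc, shift), shift)
                if _better(cand, best):
                    best = cand

    # full resolution: refine around 2x the coarse optimum
    center = best[1] * 2
    best = (-np.inf, np.zeros(3, dtype=int))
    for i in range(-2, 3):
        for j in range(-2, 3):
            for k in range(-2, 3):
                shift = np.clip(center + np.array([i, j, k]), -max_vox, max_vox)
                cand = (_ncc_at_voxel_shift(f, m, shift), shift)
                if _better(cand, best):
                    best = cand

    best_score, best_shift = best
    best_shift = best_shift.astype(float)
    if subvoxel:
        interior = tuple(slice(2, n - 2) for n in f.shape)
        for step in (0.5, 0.25):
            center_shift = best_shift.copy()
            for di in (-step, 0.0, step):
                for dj in (-step, 0.0, step):
                    for dk in (-step, 0.0, step):
                        shift = center_shift + np.array([di, dj, dk])
                        shifted = ndimage.shift(m, -shift, order=1, mode="nearest")
                        cand = (_ncc(f[interior], shifted[interior]), shift)
                        if _better(cand, (best_score, best_shift)):
                            best_score, best_shift = cand

    translation = tuple(best_shift * spacing)
    return RigidTransform(translation)


# ---------------------------------------------------------------------------
# Mask / image warping
# ---------------------------------------------------------------------------

def _sample_coords(field: DeformationField):
    """Voxel-index coordinates into the moving grid at x + d(x), shape (3, N)."""
    shape = field.grid_shape
    idx = np.indices(shape, dtype=np.float64)
    coords = np.empty_like(idx)
    for a in range(3):
        world = field.origin[a] + idx[a] * field.spacing[a] + field.displacement[..., a]
        coords[a] = (world - field.origin[a]) / field.spacing[a]
    return coords.reshape(3, -1)


def _check_grids(obj, field: DeformationField) -> None:
    if (
        obj.shape[:3] != field.grid_shape
        or not np.allclose(obj.spacing, field.spacing)
        or not np.allclose(obj.origin, field.origin)
    ):
        raise ValueError("mask/image grid does not match the deformation field grid")


def warp_mask(mask: BinaryMask, field: DeformationField, threshold: float = 0.5) -> BinaryMask:
    """Propagate a binary mask through a deformation field.

    The mask is cast to a 0/1 scalar field, resampled at x + d(x) with
    trilinear interpolation and re-binarized at ``threshold``; samples outside
    the moving grid are background.
    """
    _check_grids(mask, field)
    vals = ndimage.map_coordinates(
        mask.data.astype(np.float64),
        _sample_coords(field),
        order=1,
        mode="constant",
        cval=0.0,
    ).reshape(mask.shape)
    return BinaryMask(vals >= threshold, field.spacing, field.origin)


def warp_image(img: ImageVolume, field: DeformationField, cval: float = 0.0) -> ImageVolume:
    """Resample a scalar image through a deformation field (trilinear)."""
    _check_grids(img, field)
    vals = ndimage.map_coordinates(
        img.data, _sample_coords(field), order=1, mode="constant", cval=cval
    ).reshape(img.shape)
    return ImageVolume(vals, field.spacing, field.origin)


def invert_field(field: DeformationField, n_iter: int = 30) -> DeformationField:
    """Numerically invert a deformation field by fixed-point iteration.

    Solves d_inv(x) = -d(x + d_inv(x)); converges for smooth,
    diffeomorphic fields (Jacobian bounded away from zero).
    """
    disp = field.displacement
    inv = np.zeros_like(disp)
    idx = np.indices(field.grid_shape, dtype=np.float64)
    spacing = np.asarray(field.spacing)
    for _ in range(n_iter):
        coords = np.empty_like(idx)
        for a in range(3):
            coords[a] = idx[a] + inv[..., a] / spacing[a]
        flat = coords.reshape(3, -1)
        sampled = np.stack(
            [
                ndimage.map_coordinates(disp[..., a], flat, order=1, mode="nearest").reshape(
                    field.grid_shape
                )
                for a in range(3)
            ],
            axis=-1,
        )
        inv = -sampled
    return DeformationField(inv, field.spacing, field.origin)


def validate_field(field: DeformationField) -> FieldReport:
    """Quality report for a deformation field: Jacobian range and folding.

    The Jacobian of the map phi(x) = x + d(x) is estimated by central finite
    differences in mm; voxels with non-positive determinant are folds.
    """
    disp = field.displacement
    shape = field.grid_shape
    jac = np.zeros((*shape, 3, 3))
    for comp in range(3):
        grads = np.gradient(disp[..., comp], *field.spacing, edge_order=1)
        for ax in range(3):
            jac[..., comp, ax] = grads[ax]
    jac += np.eye(3)
    det = np.linalg.det(jac)
    max_disp = float(np.sqrt((disp**2).sum(axis=-1)).max())
    return FieldReport(
        min_jacobian=float(det.min()),
        max_jacobian=float(det.max()),
        max_displacement_mm=max_disp,
        folding_fraction=float(np.mean(det <= 0)),
    )
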