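"""Shared image containers: scalar volumes, binary masks and deformation fields.

All grids are axis-aligned.  The world coordinate (mm) of voxel ``(i, j, k)``
along axis ``a`` is ``origin[a] + index * spacing[a]``.  No direction matrix is
carried; NIfTI I/O writes and expects a diagonal affine.  By convention the
third grid axis is the cranio-caudal axis with increasing index pointing
inferiorly (configurable in the phantom generator).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

Vec3 = tuple[float, float, float]


def _as_vec3(value) -> Vec3:
    vec = tuple(float(v) for v in value)
    if len(vec) != 3:
        raise ValueError(f"expected a length-3 vector, got {value!r}")
    return vec


@dataclass(frozen=True, eq=False)
class ImageVolume:
    """A 3D scalar image (CT, activity or SUV) on a regular grid."""

    data: np.ndarray
    spacing: Vec3
    origin: Vec3 = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"image data must be 3D, got shape {data.shape}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _as_vec3(self.spacing))
        object.__setattr__(self, "origin", _as_vec3(self.origin))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def coord_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays, one per axis."""
        return tuple(
            self.axis_coords(a).reshape([-1 if i == a else 1 for i in range(3)])
            for a in range(3)
        )

    def same_grid(self, other, tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass(frozen=True, eq=False)
class BinaryMask:
    """A boolean volume sharing an :class:`ImageVolume` geometry."""

    data: np.ndarray
    spacing: Vec3
    origin: Vec3 = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got shape {data.shape}")
        object.__setattr__(self, "data", data.astype(bool))
        object.__setattr__(self, "spacing", _as_vec3(self.spacing))
        object.__setattr__(self, "origin", _as_vec3(self.origin))

    @classmethod
    def like(cls, ref: "ImageVolume | BinaryMask", data: np.ndarray) -> "BinaryMask":
        return cls(data=data, spacing=ref.spacing, origin=ref.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other, tol: float = 1e-6) -> bool:
        return ImageVolume.same_grid(self, other, tol)

    axis_coords = ImageVolume.axis_coords
    coord_grids = ImageVolume.coord_grids


@dataclass(frozen=True, eq=False)
class DeformationField:
    """Dense displacement vectors d(x) in mm on the fixed (planning) grid.

    Pull-back convention: the warped value at fixed point x is the moving
    image sampled at x + d(x).
    """

    displacement: np.ndarray  # shape (*grid_shape, 3)
    spacing: Vec3
    origin: Vec3 = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement, dtype=np.float64)
        if disp.ndim != 4 or disp.shape[-1] != 3:
            raise ValueError(
                f"displacement must have shape (nx, ny, nz, 3), got {disp.shape}"
            )
        object.__setattr__(self, "displacement", disp)
        object.__setattr__(self, "spacing", _as_vec3(self.spacing))
        object.__setattr__(self, "origin", _as_vec3(self.origin))

    @classmethod
    def identity(cls, shape, spacing, origin=(0.0, 0.0, 0.0)) -> "DeformationField":
        return cls(np.zeros((*shape, 3)), spacing, origin)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid_shape

    def same_grid(self, other, tol: float = 1e-6) -> bool:
        return (
            self.grid_shape == (other.shape[:3] if hasattr(other, "shape") else None)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.grid_shape[axis]) * self.spacing[axis]


# ---------------------------------------------------------------------------
# NIfTI I/O (diagonal affine, world units mm)
# ---------------------------------------------------------------------------

def _affine(spacing: Vec3, origin: Vec3) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _geometry_from_affine(aff: np.ndarray) -> tuple[Vec3, Vec3]:
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only diagonal (axis-aligned) NIfTI affines are supported")
    spacing = tuple(float(aff[i, i]) for i in range(3))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing in affine: {spacing}")
    origin = tuple(float(v) for v in aff[:3, 3])
    return spacing, origin


def save_image(vol: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def load_image(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing, origin = _geometry_from_affine(img.affine)
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    spacing, origin = _geometry_from_affine(img.affine)
    return BinaryMask(np.asarray(img.dataobj) > 0, spacing, origin)


def save_field(field: DeformationField, path: str | Path) -> None:
    img = nib.Nifti1Image(
        field.displacement.astype(np.float32), _affine(field.spacing, field.origin)
    )
    nib.save(img, str(path))


def load_field(path: str | Path) -> DeformationField:
    img = nib.load(str(path))
    spacing, origin = _geometry_from_affine(img.affine)
    return DeformationField(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)
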