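"""Axis-aligned 3D image grids and labeled region masks.

All volumes in this package live on axis-aligned grids described by a
voxel spacing and a physical origin, both in millimetres.  Array axes are
ordered (x, y, z); the NIfTI affine is the diagonal spacing matrix plus
the origin translation.  This covers every volume the pipeline touches
(T2w, per-b DWI channels, ADC, fBV, masks) — oblique acquisitions are out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

GLEASON_LABELS = ("GP3", "GP4Crib-", "GP4Crib+")


@dataclass(frozen=True)
class GridGeometry:
    """Spacing (mm) and origin (mm) of an axis-aligned voxel grid."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def voxel_centers(self, shape: tuple[int, int, int], axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        n = shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff

    def approx_equal(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return bool(
            np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class VolumeGrid:
    """A 3D scalar image with grid geometry.

    The carrier type for T2w images, per-b DWI channels, and ADC/fBV maps.
    """

    data: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid data must be 3D, got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.geometry.spacing

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(data=data, geometry=self.geometry)

    def physical_extent(self) -> list[tuple[float, float]]:
        """Physical span [edge, edge] covered by the grid along each axis."""
        out = []
        for ax in range(3):
            lo = self.geometry.origin[ax] - 0.5 * self.geometry.spacing[ax]
            hi = lo + self.shape[ax] * self.geometry.spacing[ax]
            out.append((lo, hi))
        return out


@dataclass
class RegionMask:
    """A binary voxel mask tied to a grid geometry, with Gleason label.

    ``volume_cc`` is always derived from the voxel count and voxel volume.
    """

    voxels: np.ndarray
    geometry: GridGeometry
    label: str = "GP3"
    region_id: str = ""
    case_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("RegionMask voxels must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cc(self) -> float:
        # 1 cc = 1000 mm^3
        return self.n_voxels * self.geometry.voxel_volume_mm3 / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def with_voxels(self, voxels: np.ndarray) -> "RegionMask":
        return replace(self, voxels=voxels)


def save_nifti(volume: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.geometry.affine())
    nib.save(img, str(path))


def load_nifti(path) -> VolumeGrid:
    img = nib.load(str(path))
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = tuple(float(abs(rot[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return VolumeGrid(
        data=np.asarray(img.get_fdata(), dtype=np.float64),
        geometry=GridGeometry(spacing=spacing, origin=origin),
    )


def save_mask_nifti(mask: RegionMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.geometry.affine())
    nib.save(img, str(path))


def load_mask_nifti(path, label: str = "GP3", region_id: str = "", case_id: str = "") -> RegionMask:
    vol = load_nifti(path)
    return RegionMask(
        voxels=vol.data > 0.5,
        geometry=vol.geometry,
        label=label,
        region_id=region_id,
        case_id=case_id,
    )
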