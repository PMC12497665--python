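"""Region-mask processing: grid resampling, slice-aware erosion, survival filtering.

The erosion step removes delineation uncertainty at region boundaries:
edge slices (slices without an occupied slice both directly above and
below) are removed entirely, and every remaining slice is eroded in 2D
with a disk whose radius guarantees that one acquisition voxel is peeled
off isotropically in-plane.  Regions left empty, or with a single voxel
(too small for feature extraction), are dropped with a reason code.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridGeometry, RegionMask, VolumeGrid

REASON_EMPTY = "empty_after_erosion"
REASON_SINGLE_VOXEL = "single_voxel"
REASON_LOST_ON_GRID = "lost_on_extraction_grid"


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class ErosionSpec:
    """Erosion radius derived from acquisition and grid in-plane voxel sizes.

    radius_voxels = ceil(acquisition / grid), never below 1: the disk always
    removes at least one full acquisition voxel from the boundary.
    """

    acquisition_inplane_mm: float
    grid_inplane_mm: float

    def __post_init__(self) -> None:
        if self.acquisition_inplane_mm <= 0 or self.grid_inplane_mm <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def radius_voxels(self) -> int:
        return max(1, math.ceil(self.acquisition_inplane_mm / self.grid_inplane_mm))


def disk_footprint(radius_voxels: int) -> np.ndarray:
    """2D disk structuring element: offsets within Euclidean distance r (in voxels)."""
    r = int(radius_voxels)
    ii, jj = np.mgrid[-r:r + 1, -r:r + 1]
    return ii ** 2 + jj ** 2 <= r ** 2


def resample_mask_to_grid(
    mask: RegionMask, target_geometry: GridGeometry, target_shape: tuple[int, int, int]
) -> RegionMask:
    """Nearest-neighbour transfer of a binary mask onto another axis-aligned grid.

    Each target voxel takes the value of the source voxel whose centre is
    nearest to the target voxel's centre; target voxels outside the source
    extent are empty.
    """
    src_ext = VolumeGrid(np.zeros(mask.shape), mask.geometry).physical_extent()
    tgt_ext = VolumeGrid(np.zeros(target_shape), target_geometry).physical_extent()
    for (slo, shi), (tlo, thi) in zip(src_ext, tgt_ext):
        if thi <= slo or tlo >= shi:
            raise GeometryError("source and target grids are physically disjoint")

    idx = []
    inside = []
    for ax in range(3):
        centers = target_geometry.origin[ax] + target_geometry.spacing[ax] * np.arange(
            target_shape[ax]
        )
        src_idx = np.round(
            (centers - mask.geometry.origin[ax]) / mask.geometry.spacing[ax]
        ).astype(int)
        ok = (src_idx >= 0) & (src_idx < mask.shape[ax])
        idx.append(np.clip(src_idx, 0, mask.shape[ax] - 1))
        inside.append(ok)
    out = mask.voxels[np.ix_(idx[0], idx[1], idx[2])]
    out &= inside[0][:, None, None] & inside[1][None, :, None] & inside[2][None, None, :]
    if not out.any():
        warnings.warn(
            f"region {mask.region_id or '<unnamed>'}: empty after resampling to target grid",
            stacklevel=2,
        )
    return RegionMask(
        voxels=out,
        geometry=target_geometry,
        label=mask.label,
        region_id=mask.region_id,
        case_id=mask.case_id,
    )


def erode_region(mask: RegionMask, spec: ErosionSpec) -> RegionMask:
    """Slice-aware cylindrical (XY-disk) erosion.

    1. Any slice lacking an occupied slice both directly above (z+1) and
       below (z-1) — judged on the region's own occupancy — is removed.
    2. Every surviving slice is eroded in 2D by a disk of
       ``spec.radius_voxels`` voxels (Euclidean, <= comparison).

    The result may be empty.
    """
    vox = mask.voxels
    occupied = vox.any(axis=(0, 1))
    has_both = np.zeros_like(occupied)
    has_both[1:-1] = occupied[1:-1] & occupied[:-2] & occupied[2:]

    out = np.zeros_like(vox)
    foot = disk_footprint(spec.radius_voxels)
    for z in np.nonzero(has_both)[0]:
        out[:, :, z] = ndimage.binary_erosion(vox[:, :, z], structure=foot)
    return mask.with_voxels(out)


def filter_regions(
    regions: list[RegionMask],
) -> tuple[list[RegionMask], list[tuple[RegionMask, str]]]:
    """Drop regions too small for feature extraction.

    Empty regions are dropped as ``empty_after_erosion``; one-voxel regions
    as ``single_voxel``; kept regions have >= 2 voxels.
    """
    kept: list[RegionMask] = []
    dropped: list[tuple[RegionMask, str]] = []
    for reg in regions:
        n = reg.n_voxels
        if n == 0:
            dropped.append((reg, REASON_EMPTY))
        elif n == 1:
            dropped.append((reg, REASON_SINGLE_VOXEL))
        else:
            kept.append(reg)
    return kept, dropped
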