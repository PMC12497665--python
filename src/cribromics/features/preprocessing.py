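"""Image normalization, grid resampling and fixed-bin-width discretization."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from ..grids import GridGeometry, VolumeGrid


class NormalizationError(ValueError):
    pass


def znormalize_image(image: VolumeGrid, scale: float = 100.0) -> VolumeGrid:
    """Z-score normalize over all image voxels: scale * (x - mean) / sd."""
    x = image.data.astype(float)
    sd = float(x.std())
    if sd == 0:
        raise NormalizationError("cannot z-normalize a constant image")
    return image.with_data(scale * (x - x.mean()) / sd)


def _to_sitk(volume: VolumeGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0), dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.geometry.origin))
    return img


def _from_sitk(img: sitk.Image) -> VolumeGrid:
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VolumeGrid(
        data=data,
        geometry=GridGeometry(spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin())),
    )


def resample_image(
    image: VolumeGrid,
    spacing: tuple[float, float, float],
    interpolator: str = "bspline",
) -> VolumeGrid:
    """Resample onto a grid with the requested spacing covering the original extent.

    ``interpolator`` is ``"bspline"`` (cubic, for images) or ``"nearest"``
    (for masks).  The output grid keeps the input origin (first voxel
    centres coincide) and has ceil(n_in * s_in / s_out) voxels per axis.
    """
    if any(s <= 0 for s in spacing):
        raise ValueError("target spacing must be positive")
    if any(n < 1 for n in image.shape):
        raise ValueError("degenerate input extent")
    interp = {"bspline": sitk.sitkBSpline, "nearest": sitk.sitkNearestNeighbor}[interpolator]
    new_size = [
        max(1, int(math.ceil(image.shape[ax] * image.spacing[ax] / spacing[ax])))
        for ax in range(3)
    ]
    img = _to_sitk(image)
    res = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        tuple(float(s) for s in spacing),
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
    )
    return _from_sitk(res)


@dataclass
class DiscretizedRegion:
    """Integer gray levels over region voxels under an absolute fixed-bin-width grid.

    level(x) = floor(x / w) - floor(min(x) / w) + 1, so levels start at 1
    and bin edges sit on the absolute multiples-of-w grid rather than being
    anchored at the region minimum.
    """

    gray_levels: np.ndarray
    n_levels: int
    bin_width: float
    level_offset: int  # floor(min/w); level L spans [(L-1+offset)*w, (L+offset)*w)

    def bin_interval(self, level: int) -> tuple[float, float]:
        lo = (level - 1 + self.level_offset) * self.bin_width
        return lo, lo + self.bin_width


def discretize_fixed_bin_width(intensities: np.ndarray, bin_width: float) -> DiscretizedRegion:
    """Discretize region intensities with a fixed bin width on an absolute grid."""
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot discretize an empty region")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    offset = int(math.floor(x.min() / bin_width))
    levels = np.floor(x / bin_width).astype(int) - offset + 1
    return DiscretizedRegion(
        gray_levels=levels,
        n_levels=int(levels.max()),
        bin_width=float(bin_width),
        level_offset=offset,
    )


def approximate_bin_bounds(lo: float, hi: float, bin_width: float) -> tuple[float, float]:
    """Intensity range expressed in bin units: (lo / w, hi / w).

    The quick arithmetic used to judge whether a bin width lands a typical
    scan in the desired 10-100 bin regime.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return lo / bin_width, hi / bin_width
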