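"""Per-region radiomics feature extraction.

Feature plan per region (153 scalars):

* ADC map  — 7 shape + 19 first-order, ADC reported in 1e-3 mm^2/s units;
* fBV map  — 7 shape + 19 first-order;
* T2w      — z-score normalized (x100), then 7 shape + 19 first-order +
             75 texture features (GLCM/GLRLM/GLSZM/NGTDM/GLDM) on the
             fixed-bin-width discretized region.

Feature names follow "<map>_<family>_<Feature>", e.g.
``adc_firstorder_90Percentile``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..grids import RegionMask, VolumeGrid
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .preprocessing import (
    DiscretizedRegion,
    approximate_bin_bounds,
    discretize_fixed_bin_width,
    resample_image,
    znormalize_image,
)
from .shape import SHAPE_NAMES, shape_features
from .texture import texture_features

__all__ = [
    "ExtractionSettings",
    "extract_region_features",
    "expected_feature_names",
    "znormalize_image",
    "resample_image",
    "discretize_fixed_bin_width",
    "approximate_bin_bounds",
    "DiscretizedRegion",
    "first_order_features",
    "shape_features",
    "texture_features",
    "FIRST_ORDER_NAMES",
    "SHAPE_NAMES",
]


@dataclass(frozen=True)
class ExtractionSettings:
    """Extraction configuration (normalization, binning, resampling)."""

    t2w_normalize: bool = True
    t2w_normalize_scale: float = 100.0
    t2w_bin_width: float = 3.0
    adc_fbv_bin_width: float = 25.0
    t2w_resample_mm: tuple[float, float, float] = (0.27, 0.27, 3.0)
    adc_fbv_resample_mm: tuple[float, float, float] = (1.03, 1.03, 2.73)
    geometry_tolerance: float = 1e-4
    surface_method: str = "mesh"
    # ADC maps are carried in mm^2/s; features are reported in units of
    # 1e-3 mm^2/s (the printed scale of prostate ADC values).
    adc_feature_scale: float = 1e3

    def __post_init__(self) -> None:
        if self.t2w_bin_width <= 0 or self.adc_fbv_bin_width <= 0:
            raise ValueError("bin widths must be positive")
        if any(s <= 0 for s in self.t2w_resample_mm + self.adc_fbv_resample_mm):
            raise ValueError("resample spacings must be positive")


def _maybe_resample(
    image: VolumeGrid, spacing: tuple[float, float, float], tol: float
) -> VolumeGrid:
    if np.allclose(image.spacing, spacing, atol=tol):
        return image
    return resample_image(image, spacing, interpolator="bspline")


def _mask_on_grid(region: RegionMask, image: VolumeGrid, tol: float) -> RegionMask:
    from ..regions import resample_mask_to_grid

    if region.geometry.approx_equal(image.geometry, tol) and region.shape == image.shape:
        return region
    return resample_mask_to_grid(region, image.geometry, image.shape)


def _levels_volume(region: RegionMask, image: VolumeGrid, bin_width: float) -> tuple[np.ndarray, int]:
    """Discretized levels on the region bounding box (0 outside the mask)."""
    idx = np.argwhere(region.voxels)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub_mask = region.voxels[box]
    disc = discretize_fixed_bin_width(image.data[box][sub_mask], bin_width)
    levels = np.zeros(sub_mask.shape, dtype=int)
    levels[sub_mask] = disc.gray_levels
    return levels, disc.n_levels


def extract_region_features(
    t2w: VolumeGrid,
    adc: VolumeGrid,
    fbv: VolumeGrid,
    region: RegionMask,
    settings: ExtractionSettings | None = None,
) -> dict[str, float]:
    """Extract the full 153-feature vector for one region.

    ``region`` must live on the ADC/fBV grid (the analysis grid) and have
    survived the region-survival filter (>= 2 voxels).
    """
    settings = settings or ExtractionSettings()
    if region.n_voxels < 2:
        raise ValueError(f"region {region.region_id}: needs >= 2 voxels for extraction")

    out: dict[str, float] = {}
    tol = settings.geometry_tolerance

    # --- ADC and fBV: shape + first order -----------------------------
    for name, vol, scale in (
        ("adc", adc, settings.adc_feature_scale),
        ("fbv", fbv, 1.0),
    ):
        img = _maybe_resample(vol, settings.adc_fbv_resample_mm, tol)
        mask = _mask_on_grid(region, img, tol)
        if mask.n_voxels < 2:
            raise ValueError(f"region {region.region_id}: lost on the {name} grid")
        vals = img.data[mask.voxels] * scale
        for feat, v in shape_features(mask, settings.surface_method).items():
            out[f"{name}_shape_{feat}"] = v
        fo = first_order_features(vals, settings.adc_fbv_bin_width, mask.geometry.voxel_volume_mm3)
        for feat, v in fo.items():
            out[f"{name}_firstorder_{feat}"] = v

    # --- T2w: shape + first order + texture ---------------------------
    img = t2w
    if settings.t2w_normalize:
        img = znormalize_image(img, settings.t2w_normalize_scale)
    img = _maybe_resample(img, settings.t2w_resample_mm, tol)
    mask = _mask_on_grid(region, img, tol)
    if mask.n_voxels < 2:
        raise ValueError(f"region {region.region_id}: lost on the T2w grid")
    vals = img.data[mask.voxels]
    for feat, v in shape_features(mask, settings.surface_method).items():
        out[f"t2w_shape_{feat}"] = v
    fo = first_order_features(vals, settings.t2w_bin_width, mask.geometry.voxel_volume_mm3)
    for feat, v in fo.items():
        out[f"t2w_firstorder_{feat}"] = v
    levels, n_levels = _levels_volume(mask, img, settings.t2w_bin_width)
    for feat, v in texture_features(levels, n_levels).items():
        out[f"t2w_{feat}"] = v
    return out


def expected_feature_names() -> list[str]:
    """The stable 153-name column order of a feature vector."""
    names: list[str] = []
    for m in ("adc", "fbv"):
        names += [f"{m}_shape_{n}" for n in SHAPE_NAMES]
        names += [f"{m}_firstorder_{n}" for n in FIRST_ORDER_NAMES]
    names += [f"t2w_shape_{n}" for n in SHAPE_NAMES]
    names += [f"t2w_firstorder_{n}" for n in FIRST_ORDER_NAMES]
    from .texture import (
        glcm_features_single,
    )

    glcm = list(glcm_features_single(np.ones((2, 2))).keys())
    glrlm = [
        "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
        "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
        "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
        "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LongRunHighGrayLevelEmphasis",
    ]
    glszm = [
        "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
        "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
        "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
        "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
        "LargeAreaHighGrayLevelEmphasis",
    ]
    ngtdm = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]
    gldm = [
        "SmallDependenceEmphasis", "LargeDependenceEmphasis", "GrayLevelNonUniformity",
        "DependenceNonUniformity", "DependenceNonUniformityNormalized",
        "GrayLevelVariance", "DependenceVariance", "DependenceEntropy",
        "LowGrayLevelEmphasis", "HighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis", "SmallDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    ]
    for fam, feats in (("glcm", glcm), ("glrlm", glrlm), ("glszm", glszm),
                       ("ngtdm", ngtdm), ("gldm", gldm)):
        names += [f"t2w_{fam}_{n}" for n in feats]
    return names
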