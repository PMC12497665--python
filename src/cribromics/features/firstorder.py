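"""First-order (intensity histogram and order-statistic) features.

Nineteen scalars per region.  Percentiles use linear interpolation between
closest ranks; Entropy and Uniformity are computed on the fixed-bin-width
discretized levels; Skewness and Kurtosis are the population moment ratios
(Kurtosis is not excess-corrected).
"""

from __future__ import annotations

import numpy as np

from .preprocessing import discretize_fixed_bin_width

FIRST_ORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile", "90Percentile",
    "Maximum", "Mean", "Median", "InterquartileRange", "Range",
    "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "StandardDeviation", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def first_order_features(
    values: np.ndarray, bin_width: float, voxel_volume_mm3: float = 1.0
) -> dict[str, float]:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("first-order features require >= 2 voxels")

    disc = discretize_fixed_bin_width(x, bin_width)
    counts = np.bincount(disc.gray_levels)[1:]
    p = counts[counts > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    mean = float(x.mean())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    m2 = float(((x - mean) ** 2).mean())
    if m2 > 0:
        skew = float(((x - mean) ** 3).mean() / m2 ** 1.5)
        kurt = float(((x - mean) ** 4).mean() / m2 ** 2)
    else:
        skew, kurt = 0.0, 0.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    energy = float((x ** 2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume_mm3 * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "StandardDeviation": float(np.sqrt(m2)),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": m2,
        "Uniformity": uniformity,
    }
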