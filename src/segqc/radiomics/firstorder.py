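"""First-order (intensity histogram) features.

All statistics are population statistics over the in-mask intensities;
entropy and uniformity are computed on the fixed-bin-width discretized
gray levels. Zero-variance ROIs get skewness and kurtosis 0. Kurtosis is
the raw fourth standardized moment (not excess kurtosis).
"""

from __future__ import annotations

import numpy as np

FEATURE_NAMES = (
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
)


def compute(
    values: np.ndarray, labels: np.ndarray, voxel_volume: float
) -> dict[str, float]:
    x = np.asarray(values, dtype=float)
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    energy = float(np.sum(x**2))
    if var > 0:
        std = np.sqrt(var)
        skew = float(np.mean((x - mean) ** 3) / std**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)
    else:
        skew, kurt = 0.0, 0.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    counts = np.bincount(np.asarray(labels, dtype=np.int64))[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": entropy,
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Skewness": skew,
        "TotalEnergy": float(voxel_volume * energy),
        "Uniformity": uniformity,
        "Variance": float(var),
    }
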