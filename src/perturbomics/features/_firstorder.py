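"""First-order intensity statistics (18) over the ROI voxels.

Entropy and Uniformity operate on the discretized gray levels (fixed bin
width, shared with the texture features); everything else on the raw
intensities. Moments are population moments; Kurtosis is *not*
excess-corrected (a Gaussian scores 3).
"""

from __future__ import annotations

import numpy as np

FIRSTORDER_NAMES = [
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
]

_EPS = np.finfo(np.float64).tiny


def firstorder_features(
    values: np.ndarray, voxel_volume_mm3: float, bin_width: float
) -> dict[str, float]:
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("first-order features of an empty ROI are undefined")
    n = x.size
    out: dict[str, float] = {}
    out["Energy"] = float(np.sum(x**2))
    out["TotalEnergy"] = voxel_volume_mm3 * out["Energy"]

    # discretized histogram for Entropy / Uniformity
    levels = np.floor(x / bin_width) - np.floor(x.min() / bin_width)
    _, counts = np.unique(levels, return_counts=True)
    p = counts / n
    out["Entropy"] = float(-np.sum(p * np.log2(p + _EPS)))
    out["Uniformity"] = float(np.sum(p**2))

    out["Minimum"] = float(x.min())
    out["10Percentile"] = float(np.percentile(x, 10))
    out["90Percentile"] = float(np.percentile(x, 90))
    out["Maximum"] = float(x.max())
    mean = float(x.mean())
    out["Mean"] = mean
    out["Median"] = float(np.median(x))
    p25, p75 = np.percentile(x, [25, 75])
    out["InterquartileRange"] = float(p75 - p25)
    out["Range"] = out["Maximum"] - out["Minimum"]
    out["MeanAbsoluteDeviation"] = float(np.abs(x - mean).mean())
    p10, p90 = out["10Percentile"], out["90Percentile"]
    inner = x[(x >= p10) & (x <= p90)]
    out["RobustMeanAbsoluteDeviation"] = (
        float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0
    )
    out["RootMeanSquared"] = float(np.sqrt(np.mean(x**2)))
    var = float(np.mean((x - mean) ** 2))
    out["Variance"] = var
    if var > 0:
        m3 = float(np.mean((x - mean) ** 3))
        m4 = float(np.mean((x - mean) ** 4))
        out["Skewness"] = m3 / var**1.5
        out["Kurtosis"] = m4 / var**2
    else:
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0
    return out
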