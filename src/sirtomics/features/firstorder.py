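"""First-order (intensity histogram / statistics) features, 18 in total.

Entropy and Uniformity operate on the fixed-bin-width discretized histogram;
everything else on the raw in-mask intensities. Moments are population
moments (ddof=0), matching standard radiomics extractor conventions.
"""

from __future__ import annotations

import numpy as np

FIRSTORDER_FEATURES = [
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


def firstorder_features(values: np.ndarray, bin_width: float,
                        voxel_volume_mm3: float) -> dict[str, float]:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    sd = np.sqrt(var)

    # discretized probabilities for Entropy / Uniformity
    lo = np.floor(x.min() / bin_width)
    levels = np.floor(x / bin_width) - lo
    counts = np.bincount(levels.astype(int))
    p = counts[counts > 0] / n

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if robust.size:
        rmad = np.abs(robust - robust.mean()).mean()
    else:
        rmad = 0.0
    if sd > 0:
        skew = np.mean((x - mean) ** 3) / sd**3
        kurt = np.mean((x - mean) ** 4) / var**2  # non-excess kurtosis
    else:
        skew, kurt = 0.0, 0.0

    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume_mm3 * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(rmad),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }
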