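"""First-order (intensity histogram) features."""

from __future__ import annotations

import numpy as np

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def firstorder_features(values: np.ndarray, mask: np.ndarray, bin_width: float,
                        voxel_volume_mm3: float) -> dict[str, float]:
    x = values[mask].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    # discretized histogram for entropy/uniformity (fixed bin width anchored
    # at the region minimum)
    levels = np.floor((x - x.min()) / bin_width).astype(np.int64)
    p = np.bincount(levels).astype(np.float64) / n
    pnz = p[p > 0]
    entropy = float(-(pnz * np.log2(pnz)).sum())

    robust = x[(x >= p10) & (x <= p90)]
    energy = float((x**2).sum())

    out = {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume_mm3,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(((x - mean) ** 3).mean() / sd**3) if sd > 0 else 0.0,
        "Kurtosis": float(((x - mean) ** 4).mean() / var**2) if var > 0 else 0.0,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
    return out
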