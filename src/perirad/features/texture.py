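"""Feature formulas over the gray-level texture matrices.

Definitions follow the image-biomarker standardization conventions
(entropies in bits, merged-direction matrices).  Degenerate regions (single
gray level, zero variance) return the conventional limit values rather than
NaN, so a constant patch yields contrast 0, correlation 1, etc.
"""

from __future__ import annotations

import numpy as np

from . import matrices as mx

_EPS = np.finfo(np.float64).eps


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------- GLCM

def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    C = mx.glcm_matrix(levels, mask, n_levels)
    total = C.sum()
    if total == 0:  # single in-mask voxel: no pairs at all
        return {name: 0.0 for name in GLCM_NAMES}
    P = C / total
    Ng = n_levels
    i = np.arange(1, Ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sx = float(np.sqrt(((i - ux) ** 2 * px).sum()))
    sy = float(np.sqrt(((i - uy) ** 2 * py).sum()))

    ksum = np.arange(2, 2 * Ng + 1)
    p_sum = np.zeros(ksum.size)
    np.add.at(p_sum, (I + J).ravel() - 2, P.ravel())
    kdiff = np.arange(0, Ng)
    p_diff = np.zeros(Ng)
    np.add.at(p_diff, np.abs(I - J).ravel(), P.ravel())

    out: dict[str, float] = {}
    out["Autocorrelation"] = float((I * J * P).sum())
    out["JointAverage"] = ux
    out["ClusterProminence"] = float(((I + J - ux - uy) ** 4 * P).sum())
    out["ClusterShade"] = float(((I + J - ux - uy) ** 3 * P).sum())
    out["ClusterTendency"] = float(((I + J - ux - uy) ** 2 * P).sum())
    out["Contrast"] = float(((I - J) ** 2 * P).sum())
    if sx * sy > _EPS:
        out["Correlation"] = float((out["Autocorrelation"] - ux * uy) / (sx * sy))
    else:
        out["Correlation"] = 1.0
    da = float((kdiff * p_diff).sum())
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = _entropy(p_diff)
    out["DifferenceVariance"] = float(((kdiff - da) ** 2 * p_diff).sum())
    out["JointEnergy"] = float((P**2).sum())
    hxy = _entropy(P.ravel())
    out["JointEntropy"] = hxy

    pxy = np.outer(px, py)
    nz = P > 0
    hxy1 = float(-(P[nz] * np.log2(pxy[nz] + _EPS)).sum())
    hxy2 = _entropy(pxy.ravel())
    hx = _entropy(px)
    hy = _entropy(py)
    denom = max(hx, hy)
    out["Imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    out["Idm"] = float((P / (1.0 + (I - J) ** 2)).sum())
    out["Idmn"] = float((P / (1.0 + ((I - J) / Ng) ** 2)).sum())
    out["Id"] = float((P / (1.0 + np.abs(I - J))).sum())
    out["Idn"] = float((P / (1.0 + np.abs(I - J) / Ng)).sum())
    offdiag = I != J
    out["InverseVariance"] = float((P[offdiag] / (I[offdiag] - J[offdiag]) ** 2).sum())
    out["MaximumProbability"] = float(P.max())
    out["SumAverage"] = float((ksum * p_sum).sum())
    out["SumEntropy"] = _entropy(p_sum)
    out["SumSquares"] = float(((I - ux) ** 2 * P).sum())

    if Ng > 1 and (px > 0).sum() > 1:
        px_safe = np.where(px > 0, px, 1.0)
        py_safe = np.where(py > 0, py, 1.0)
        # Q[i, j] = sum_k P[i, k] P[j, k] / (px[i] py[k])
        Q = (P / px_safe[:, None]) @ (P.T / py_safe[:, None])
        eig = np.sort(np.abs(np.linalg.eigvals(Q)))[::-1]
        out["MCC"] = float(np.sqrt(max(0.0, eig[1]))) if eig.size > 1 else 1.0
    else:
        out["MCC"] = 1.0
    return out


GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)


# ---------------------------------------------------------------- GLRLM

def _rl_style_features(M: np.ndarray, n_sites: float, prefix: dict[str, str]) -> dict[str, float]:
    """Shared formulas for run-length / size-zone / dependence matrices.

    ``M[g-1, j-1]`` counts runs/zones/dependencies of gray level g and
    size j; ``n_sites`` normalizes the percentage-style feature.
    """
    N = M.sum()
    if N == 0:
        return {}
    p = M / N
    Ng, Nj = M.shape
    g = np.arange(1, Ng + 1, dtype=float)
    j = np.arange(1, Nj + 1, dtype=float)
    G, Jm = np.meshgrid(g, j, indexing="ij")
    pg = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_g = float((g * pg).sum())
    mu_j = float((j * pj).sum())

    out: dict[str, float] = {}
    out[prefix["small"]] = float((p / Jm**2).sum())
    out[prefix["large"]] = float((p * Jm**2).sum())
    out[prefix["gln"]] = float((M.sum(axis=1) ** 2).sum() / N)
    if prefix.get("glnn"):
        out[prefix["glnn"]] = float((pg**2).sum())
    out[prefix["sn"]] = float((M.sum(axis=0) ** 2).sum() / N)
    if prefix.get("snn"):
        out[prefix["snn"]] = float((pj**2).sum())
    if prefix.get("pct"):
        out[prefix["pct"]] = float(N / n_sites)
    out[prefix["glv"]] = float(((G - mu_g) ** 2 * p).sum())
    out[prefix["sv"]] = float(((Jm - mu_j) ** 2 * p).sum())
    out[prefix["entropy"]] = _entropy(p.ravel())
    out[prefix["lgl"]] = float((p / G**2).sum())
    out[prefix["hgl"]] = float((p * G**2).sum())
    out[prefix["slgl"]] = float((p / (G**2 * Jm**2)).sum())
    out[prefix["shgl"]] = float((p * G**2 / Jm**2).sum())
    out[prefix["llgl"]] = float((p * Jm**2 / G**2).sum())
    out[prefix["lhgl"]] = float((p * G**2 * Jm**2).sum())
    return out


def glrlm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    R = mx.glrlm_matrix(levels, mask, n_levels)
    n_sites = float(mask.sum()) * len(mx.DIRECTIONS)
    return _rl_style_features(R, n_sites, {
        "small": "ShortRunEmphasis",
        "large": "LongRunEmphasis",
        "gln": "GrayLevelNonUniformity",
        "glnn": "GrayLevelNonUniformityNormalized",
        "sn": "RunLengthNonUniformity",
        "snn": "RunLengthNonUniformityNormalized",
        "pct": "RunPercentage",
        "glv": "GrayLevelVariance",
        "sv": "RunVariance",
        "entropy": "RunEntropy",
        "lgl": "LowGrayLevelRunEmphasis",
        "hgl": "HighGrayLevelRunEmphasis",
        "slgl": "ShortRunLowGrayLevelEmphasis",
        "shgl": "ShortRunHighGrayLevelEmphasis",
        "llgl": "LongRunLowGrayLevelEmphasis",
        "lhgl": "LongRunHighGrayLevelEmphasis",
    })


def glszm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    S = mx.glszm_matrix(levels, mask, n_levels)
    return _rl_style_features(S, float(mask.sum()), {
        "small": "SmallAreaEmphasis",
        "large": "LargeAreaEmphasis",
        "gln": "GrayLevelNonUniformity",
        "glnn": "GrayLevelNonUniformityNormalized",
        "sn": "SizeZoneNonUniformity",
        "snn": "SizeZoneNonUniformityNormalized",
        "pct": "ZonePercentage",
        "glv": "GrayLevelVariance",
        "sv": "ZoneVariance",
        "entropy": "ZoneEntropy",
        "lgl": "LowGrayLevelZoneEmphasis",
        "hgl": "HighGrayLevelZoneEmphasis",
        "slgl": "SmallAreaLowGrayLevelEmphasis",
        "shgl": "SmallAreaHighGrayLevelEmphasis",
        "llgl": "LargeAreaLowGrayLevelEmphasis",
        "lhgl": "LargeAreaHighGrayLevelEmphasis",
    })


def gldm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    D = mx.gldm_matrix(levels, mask, n_levels)
    # 14 features: the dependence family omits the normalized gray-level
    # non-uniformity and the percentage (every voxel has a dependence)
    feats = _rl_style_features(D, float(mask.sum()), {
        "small": "SmallDependenceEmphasis",
        "large": "LargeDependenceEmphasis",
        "gln": "GrayLevelNonUniformity",
        "sn": "DependenceNonUniformity",
        "snn": "DependenceNonUniformityNormalized",
        "glv": "GrayLevelVariance",
        "sv": "DependenceVariance",
        "entropy": "DependenceEntropy",
        "lgl": "LowGrayLevelEmphasis",
        "hgl": "HighGrayLevelEmphasis",
        "slgl": "SmallDependenceLowGrayLevelEmphasis",
        "shgl": "SmallDependenceHighGrayLevelEmphasis",
        "llgl": "LargeDependenceLowGrayLevelEmphasis",
        "lhgl": "LargeDependenceHighGrayLevelEmphasis",
    })
    return feats


# ---------------------------------------------------------------- NGTDM

def ngtdm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    n_g, s_g = mx.ngtdm_table(levels, mask, n_levels)
    Nvp = n_g.sum()
    out = {name: 0.0 for name in NGTDM_NAMES}
    if Nvp == 0:
        return out
    p = n_g / Nvp
    g = np.arange(1, n_levels + 1, dtype=float)
    nz = p > 0
    Ngp = int(nz.sum())

    coarse_den = float((p * s_g).sum())
    out["Coarseness"] = float(1.0 / coarse_den) if coarse_den > 0 else 1e6

    if Ngp > 1:
        gi = g[nz]
        pi = p[nz]
        si = s_g[nz]
        PI, PJ = np.meshgrid(pi, pi, indexing="ij")
        GI, GJ = np.meshgrid(gi, gi, indexing="ij")
        out["Contrast"] = float(
            (PI * PJ * (GI - GJ) ** 2).sum() / (Ngp * (Ngp - 1)) * (s_g.sum() / Nvp)
        )
        busy_den = float(np.abs(GI * PI - GJ * PJ).sum())
        out["Busyness"] = float((p * s_g).sum() / busy_den) if busy_den > 0 else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            comp = (np.abs(GI - GJ) / (PI + PJ)) * (PI * si[:, None] + PJ * si[None, :])
        out["Complexity"] = float(comp.sum() / Nvp)
        strength_num = float(((PI + PJ) * (GI - GJ) ** 2).sum())
        ssum = float(s_g.sum())
        out["Strength"] = strength_num / ssum if ssum > 0 else 0.0
    return out


NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
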