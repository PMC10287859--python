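"""Derived-image filters applied before intensity-feature computation.

All filters map a 3-D array to one or more arrays of the same shape, so the
mask applies unchanged.  Intensity transforms are scaled to keep the output
range comparable to the input and, above all, finite; bit-for-bit agreement
with any particular extractor is a non-goal.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import local_binary_pattern

_SQRT2 = np.sqrt(2.0)


def _haar_1d(arr: np.ndarray, axis: int, high: bool) -> np.ndarray:
    # undecimated single-level Haar step (reflected boundaries)
    w = np.array([-1.0, 1.0]) / _SQRT2 if high else np.array([1.0, 1.0]) / _SQRT2
    return ndimage.correlate1d(arr, w, axis=axis, mode="reflect")


def wavelet_subbands(values: np.ndarray) -> dict[str, np.ndarray]:
    """Eight sub-bands of an undecimated single-level Haar transform.

    Keyed 'LLL'…'HHH'; letter i selects low/high pass along axis i.
    """
    out: dict[str, np.ndarray] = {}
    ax0 = {"L": _haar_1d(values, 0, False), "H": _haar_1d(values, 0, True)}
    for c0, a0 in ax0.items():
        ax1 = {"L": _haar_1d(a0, 1, False), "H": _haar_1d(a0, 1, True)}
        for c1, a1 in ax1.items():
            for c2 in "LH":
                out[c0 + c1 + c2] = _haar_1d(a1, 2, c2 == "H")
    return out


def _absmax(values: np.ndarray) -> float:
    return float(np.abs(values).max())


def square_image(values: np.ndarray) -> np.ndarray:
    m = _absmax(values)
    return values**2 / m if m > 0 else np.zeros_like(values)


def squareroot_image(values: np.ndarray) -> np.ndarray:
    m = _absmax(values)
    return np.sign(values) * np.sqrt(np.abs(values) * m) if m > 0 else np.zeros_like(values)


def logarithm_image(values: np.ndarray) -> np.ndarray:
    m = _absmax(values)
    if m == 0:
        return np.zeros_like(values)
    scale = m / np.log1p(m)
    return np.sign(values) * np.log1p(np.abs(values)) * scale


def exponential_image(values: np.ndarray) -> np.ndarray:
    m = _absmax(values)
    if m == 0:
        return np.ones_like(values)
    return np.exp(np.abs(values) / m * np.log1p(m))


def gradient_image(values: np.ndarray, spacing) -> np.ndarray:
    grads = np.gradient(values, *spacing)
    return np.sqrt(sum(g**2 for g in grads))


def lbp2d_image(values: np.ndarray, n_points: int = 8, radius: float = 1.0) -> np.ndarray:
    """Slice-wise (last axis) uniform local binary pattern codes."""
    import warnings

    out = np.empty_like(values)
    with warnings.catch_warnings():
        # float input warning: codes on smooth float images are exactly what
        # we want here
        warnings.simplefilter("ignore", UserWarning)
        for k in range(values.shape[2]):
            out[:, :, k] = local_binary_pattern(values[:, :, k], P=n_points, R=radius, method="uniform")
    return out


def lbp3d_image(values: np.ndarray) -> np.ndarray:
    """Coarse 3-D LBP: per voxel, the count of 26-neighbours exceeding it."""
    count = np.zeros_like(values)
    padded = np.pad(values, 1, mode="edge")
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                shifted = padded[1 + dx : 1 + dx + values.shape[0],
                                 1 + dy : 1 + dy + values.shape[1],
                                 1 + dz : 1 + dz + values.shape[2]]
                count += shifted > values
    return count


def log_image(values: np.ndarray, spacing, sigma_mm: float) -> np.ndarray:
    """Laplacian-of-Gaussian response at a physical scale."""
    return ndimage.gaussian_laplace(values, sigma=[sigma_mm / s for s in spacing])


def derived_images(values: np.ndarray, spacing, config) -> dict[str, np.ndarray]:
    """All configured derived images, keyed by image-type name."""
    from .config import image_types

    out: dict[str, np.ndarray] = {}
    subbands: dict[str, np.ndarray] | None = None
    for name in image_types(config):
        if name == "original":
            out[name] = values
        elif name.startswith("wavelet-"):
            if subbands is None:
                subbands = wavelet_subbands(values)
            out[name] = subbands[name.split("-", 1)[1]]
        elif name.startswith("log-sigma-"):
            sigma = float(name[len("log-sigma-"):-2])
            out[name] = log_image(values, spacing, sigma)
        elif name == "square":
            out[name] = square_image(values)
        elif name == "squareroot":
            out[name] = squareroot_image(values)
        elif name == "logarithm":
            out[name] = logarithm_image(values)
        elif name == "exponential":
            out[name] = exponential_image(values)
        elif name == "gradient":
            out[name] = gradient_image(values, spacing)
        elif name == "lbp-2D":
            out[name] = lbp2d_image(values)
        elif name == "lbp-3D":
            out[name] = lbp3d_image(values)
        else:  # pragma: no cover
            raise ValueError(f"unhandled image type {name}")
    return out
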