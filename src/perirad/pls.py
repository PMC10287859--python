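"""Partial least squares (PLS1) regression with per-feature β coefficients.

A NIPALS implementation that exposes the whole component path: one pass at
``k_max`` yields the coefficient vector for every smaller component count,
which the nested cross-validation exploits.  At ``k = rank(X)`` (and
``n > p``) the coefficients coincide with ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSFit", "pls1_path", "fit_pls", "predict", "top_beta_fraction", "profile_top_features"]

_TOL = 1e-12


def pls1_path(X: np.ndarray, y: np.ndarray, k_max: int) -> np.ndarray:
    """Coefficient paths of PLS1 on *centered* data.

    Returns an array of shape ``(k_max, p)``; row ``a`` holds the
    coefficients using ``a + 1`` components.  If the deflated predictors
    degenerate before ``k_max`` components, later rows repeat the last
    attainable solution.
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    n, p = X.shape
    betas = np.zeros((k_max, p))
    W = np.empty((p, k_max))
    P = np.empty((p, k_max))
    q = np.empty(k_max)
    # R = P^T W is unit-diagonal upper triangular for PLS1 (each weight
    # vector is orthogonal to all earlier loadings), so the coefficient
    # system solves by back-substitution
    R = np.zeros((k_max, k_max))
    scale = max(float(np.abs(X).max()), 1.0)
    for a in range(k_max):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= _TOL * scale:
            if a > 0:
                betas[a:] = betas[a - 1]
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= _TOL:
            if a > 0:
                betas[a:] = betas[a - 1]
            break
        p_a = X.T @ t
        p_a /= tt
        q_a = float(y @ t) / tt
        X -= t[:, None] * p_a[None, :]
        y -= q_a * t
        W[:, a] = w
        P[:, a] = p_a
        q[a] = q_a
        R[: a + 1, a] = P[:, : a + 1].T @ w
        R[a, a] = 1.0
        # back-substitution for alpha in R[:a+1, :a+1] @ alpha = q[:a+1]
        alpha = q[: a + 1].copy()
        for row in range(a - 1, -1, -1):
            alpha[row] -= R[row, row + 1 : a + 1] @ alpha[row + 1 : a + 1]
        betas[a] = W[:, : a + 1] @ alpha
    return betas


@dataclass
class PLSFit:
    """A fitted PLS1 model on (standardized) features."""

    n_components: int
    beta: np.ndarray
    intercept: float
    feature_keys: list = field(default_factory=list)
    x_mean: np.ndarray | None = None


def fit_pls(X, y, k: int, feature_keys=None) -> PLSFit:
    """Fit PLS1 of a {0,1} outcome on a feature matrix with ``k`` components."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"X has {n} rows but y has {len(y)}")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome vector contains a single class")
    k_bound = min(n - 1, p)
    if not (1 <= k <= k_bound):
        raise ValueError(f"k must be in [1, {k_bound}], got {k}")
    xm = X.mean(axis=0)
    ym = float(y.mean())
    beta = pls1_path(X - xm, y - ym, k)[k - 1]
    intercept = ym - float(xm @ beta)
    keys = list(feature_keys) if feature_keys is not None else list(range(p))
    return PLSFit(n_components=k, beta=beta, intercept=intercept, feature_keys=keys, x_mean=xm)


def predict(fit: PLSFit, X) -> np.ndarray:
    """Continuous risk scores ``intercept + X @ beta`` (no thresholding)."""
    if hasattr(X, "columns"):
        if list(X.columns) != list(fit.feature_keys):
            raise ValueError("prediction columns do not match the fitted feature keys")
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != fit.beta.size:
        raise ValueError(f"expected {fit.beta.size} features, got {X.shape[1]}")
    return fit.intercept + X @ fit.beta


def top_beta_fraction(fit: PLSFit, fraction: float = 0.05) -> list:
    """The ``floor(fraction * p)`` feature keys with largest ``|beta|``.

    Sorted by descending magnitude; exact ties are broken by ascending key
    order so the result is deterministic.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    p = fit.beta.size
    m = int(np.floor(fraction * p))
    order = sorted(range(p), key=lambda idx: (-abs(fit.beta[idx]), _sort_key(fit.feature_keys[idx])))
    return [fit.feature_keys[idx] for idx in order[:m]]


def _sort_key(key):
    if isinstance(key, tuple):
        return tuple(str(x) for x in key)
    return (str(key),)


def profile_top_features(keys) -> dict:
    """Tabulate provenance counts of ranked feature keys.

    Keys must be 6-tuples ``(phase, compartment, resolution_mm, filter,
    feature_class, feature_name)``.  Classes are grouped as shape /
    first-order / texture (second-order).
    """
    profile = {
        "n": len(keys),
        "compartment": {},
        "phase": {},
        "resolution_mm": {},
        "class_group": {},
    }
    for key in keys:
        phase, compartment, resolution, _filter, cls, _name = key
        group = (
            "shape" if cls == "shape"
            else "firstorder" if cls == "firstorder"
            else "texture"
        )
        for field_name, value in (
            ("compartment", compartment),
            ("phase", phase),
            ("resolution_mm", resolution),
            ("class_group", group),
        ):
            bucket = profile[field_name]
            bucket[value] = bucket.get(value, 0) + 1
    return profile
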