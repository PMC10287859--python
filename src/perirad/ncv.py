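"""Leave-one-out nested cross-validation for the PLS risk model.

Outer loop: hold out one subject, fit on the rest, score the held-out
subject.  Inner loop: leave-one-out over the outer training set to pick the
component count maximizing the inner AUC (ties toward the smallest k).
Standardization is refit inside each outer training fold by default; a
``zscore_mode='global'`` option standardizes once on the full table (the
leakier convention sometimes used with small cohorts).

The whole procedure is deterministic: there is no internal randomness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import pls1_path
from .significance import roc_auc

__all__ = ["NCVResult", "default_k_grid", "inner_select_k", "loo_ncv"]


@dataclass
class NCVResult:
    subjects: list
    scores: np.ndarray  # one out-of-sample score per subject
    fold_k: list[int]  # selected component count per outer fold
    inner_auc: list[dict]  # per-fold {k: inner AUC}
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject": self.subjects, "oos_score": self.scores, "selected_k": self.fold_k}
        )


def default_k_grid(n_train: int, p: int, k_cap: int = 30) -> list[int]:
    k_max = min(k_cap, n_train - 2, p)
    return list(range(1, max(k_max, 1) + 1))


def _loo_predictions(X: np.ndarray, y: np.ndarray, k_grid: list[int]) -> tuple[np.ndarray, list[int]]:
    """Leave-one-out predictions for every k in the grid.

    Returns ``(preds, valid_rows)`` where ``preds[j, i]`` is subject j's
    prediction using ``k_grid[i]`` components.  Rows whose training set
    degenerates to a single class are dropped (flagged by the caller).
    """
    n, p = X.shape
    k_max = min(max(k_grid), n - 2, p)
    preds = np.full((n, len(k_grid)), np.nan)
    valid = []
    for j in range(n):
        keep = np.arange(n) != j
        yt = y[keep]
        if yt.min() == yt.max():
            continue
        Xt = X[keep]
        xm = Xt.mean(axis=0)
        ym = yt.mean()
        betas = pls1_path(Xt - xm, yt - ym, k_max)
        for i, k in enumerate(k_grid):
            b = betas[min(k, k_max) - 1]
            preds[j, i] = ym + (X[j] - xm) @ b
        valid.append(j)
    return preds, valid


def inner_select_k(X_train: np.ndarray, y_train: np.ndarray, k_grid: list[int]) -> tuple[int, dict]:
    """Component count with maximal inner leave-one-out AUC.

    Ties (within float tolerance) break toward the smallest k.  Returns the
    selected k and the per-k AUC map.
    """
    if not k_grid:
        raise ValueError("k_grid is empty")
    k_grid = sorted(set(int(k) for k in k_grid))
    preds, valid = _loo_predictions(np.asarray(X_train, float), np.asarray(y_train, float), k_grid)
    if len(valid) < 2:
        raise ValueError("inner loop degenerate: fewer than 2 valid folds")
    yv = np.asarray(y_train)[valid]
    if yv.min() == yv.max():
        # every fold of the minority class was skipped (single-class inner
        # training); no inner AUC is computable — fall back to parsimony
        warnings.warn("inner validation labels single-class; returning the smallest k")
        return k_grid[0], {}
    aucs = {}
    for i, k in enumerate(k_grid):
        aucs[k] = roc_auc(preds[valid, i], yv)
    best = max(aucs.values())
    if all(abs(a - best) < 1e-12 for a in aucs.values()) and len(k_grid) > 1:
        warnings.warn("inner AUC identical for all k; returning the smallest")
    selected = min(k for k, a in aucs.items() if a >= best - 1e-12)
    return selected, aucs


def loo_ncv(
    table,
    labels,
    k_grid: list[int] | None = None,
    zscore_mode: str = "fold",
    column_selector=None,
    predict_table=None,
) -> NCVResult:
    """Leave-one-out nested cross-validation.

    Parameters
    ----------
    table : DataFrame or ndarray
        Subjects × features.  All model inputs for fold i derive only from
        the other subjects' rows.
    labels : binary outcome per subject.
    k_grid : candidate component counts (default 1..min(30, n−2, p)).
    zscore_mode : 'fold' (refit standardization per outer training fold) or
        'global' (standardize once on all subjects before the loop).
    column_selector : optional callable ``f(train_row_labels) -> columns``
        recomputing feature selection within each outer training fold.
    predict_table : optional table supplying the held-out rows at predict
        time (defaults to ``table``); used by the leakage audit.
    """
    if zscore_mode not in ("fold", "global"):
        raise ValueError(f"zscore_mode must be 'fold' or 'global', got {zscore_mode}")
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(np.asarray(table, float))
    pred_df = df if predict_table is None else (
        predict_table if isinstance(predict_table, pd.DataFrame) else pd.DataFrame(np.asarray(predict_table, float))
    )
    if not pred_df.index.equals(df.index) or not pred_df.columns.equals(df.columns):
        raise ValueError("predict_table must share the table's rows and columns")
    y = np.asarray(labels, dtype=float)
    n = len(df)
    if n < 4:
        raise ValueError(f"need at least 4 subjects, got {n}")
    if len(y) != n:
        raise ValueError("labels length does not match the table")
    if y.min() == y.max():
        raise ValueError("both classes must be present")

    if zscore_mode == "global":
        mu_g = df.mean(axis=0)
        sd_g = df.std(axis=0, ddof=1)
        keep_g = sd_g > 0

    subjects = list(df.index)
    scores = np.empty(n)
    fold_k: list[int] = []
    inner_aucs: list[dict] = []
    flags: list[str] = []

    for i in range(n):
        train = np.arange(n) != i
        cols = df.columns
        if column_selector is not None:
            cols = pd.Index(column_selector(df.index[train]))
        Xfull = df[cols]
        Xp_row = pred_df[cols].iloc[[i]]

        if zscore_mode == "fold":
            mu = Xfull.iloc[train].mean(axis=0)
            sd = Xfull.iloc[train].std(axis=0, ddof=1)
            keep = sd > 0
        else:
            mu = mu_g[cols]
            sd = sd_g[cols]
            keep = keep_g[cols]
        Xs = ((Xfull.loc[:, keep] - mu[keep]) / sd[keep]).to_numpy(float)
        x_i = ((Xp_row.loc[:, keep] - mu[keep]) / sd[keep]).to_numpy(float)[0]

        X_train = Xs[train]
        y_train = y[train]
        if y_train.min() == y_train.max():
            flags.append(f"outer fold {i}: training set single-class")
            scores[i] = np.nan
            fold_k.append(0)
            inner_aucs.append({})
            continue

        grid = k_grid if k_grid is not None else default_k_grid(len(y_train), X_train.shape[1])
        grid = [k for k in grid if 1 <= k <= min(len(y_train) - 1, X_train.shape[1])]
        if not grid:
            raise ValueError("k_grid contains no feasible component counts")

        k_sel, aucs = inner_select_k(X_train, y_train, grid)
        xm = X_train.mean(axis=0)
        ym = y_train.mean()
        beta = pls1_path(X_train - xm, y_train - ym, k_sel)[k_sel - 1]
        scores[i] = ym + (x_i - xm) @ beta
        fold_k.append(k_sel)
        inner_aucs.append(aucs)

    return NCVResult(subjects=subjects, scores=scores, fold_k=fold_k, inner_auc=inner_aucs, flags=flags)
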