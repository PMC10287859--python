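"""Inter-reader repeatability filtering and the consensus modeling table."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RepeatabilityReport",
    "repeatability_filter",
    "consensus_table",
    "mean_abs_correlation",
]


@dataclass
class RepeatabilityReport:
    r: pd.Series  # per-feature correlation between readers (NaN = undefined)
    selected: list
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame({
            "r": self.r,
            "selected": [k in sel for k in self.r.index],
        })


def _check_aligned(table1: pd.DataFrame, table2: pd.DataFrame) -> None:
    if not table1.columns.equals(table2.columns):
        raise ValueError("feature tables have different column keys")
    if not table1.index.equals(table2.index):
        raise ValueError("feature tables have different subject rows")
    if len(table1) < 3:
        raise ValueError(f"need at least 3 subjects, got {len(table1)}")


def repeatability_filter(
    table1: pd.DataFrame, table2: pd.DataFrame, threshold: float = 0.95
) -> RepeatabilityReport:
    """Select features whose between-reader product-moment correlation
    across subjects strictly exceeds ``threshold``.

    Features with undefined correlation (zero variance in either table) are
    excluded.
    """
    _check_aligned(table1, table2)
    a = table1.to_numpy(dtype=float)
    b = table2.to_numpy(dtype=float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.sqrt((a**2).sum(axis=0))
    sb = np.sqrt((b**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a * b).sum(axis=0) / (sa * sb)
    r[(sa == 0) | (sb == 0)] = np.nan
    r_series = pd.Series(r, index=table1.columns)
    selected = list(table1.columns[np.nan_to_num(r, nan=-np.inf) > threshold])
    return RepeatabilityReport(r=r_series, selected=selected, threshold=threshold)


def consensus_table(
    table1: pd.DataFrame, table2: pd.DataFrame, selected, mode: str = "mean"
) -> pd.DataFrame:
    """Per-subject consensus values over the selected keys.

    ``mode='mean'`` averages the two readers (default); ``mode='reader1'``
    passes reader 1 through for sensitivity analysis.
    """
    if len(selected) == 0:
        raise ValueError(
            "no features selected; relax the repeatability threshold or reduce reader perturbation"
        )
    for key in selected:
        if key not in table1.columns or key not in table2.columns:
            raise KeyError(f"selected key {key} missing from a reader table")
    sel = list(selected)
    if mode == "mean":
        return (table1[sel] + table2[sel]) / 2.0
    if mode == "reader1":
        return table1[sel].copy()
    raise ValueError(f"unknown consensus mode {mode!r}")


def mean_abs_correlation(table: pd.DataFrame) -> float:
    """Mean absolute pairwise correlation over all unordered feature pairs."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(table) < 3:
        raise ValueError("need at least 3 subjects")
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        warnings.warn(f"excluding {int((sd == 0).sum())} constant columns from correlation")
        x = x[:, sd > 0]
        if x.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant features")
    corr = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    return float(np.abs(corr[iu]).mean())
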