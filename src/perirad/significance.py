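"""ROC/AUC and permutation-null significance of out-of-sample scores.

The null distribution shuffles the label vector against the *fixed* scores
and records the AUC of each arrangement; an observed AUC is converted to a
z-score against the null mean and standard deviation (sample sd, n−1
denominator) and to one-sided upper-tail p-values, both normal-theory and
empirical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PermutationNull", "roc_auc", "permutation_null", "auc_significance"]


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("both classes must be present")
    return scores, labels.astype(int), n_pos


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve = Mann–Whitney concordance, ties counted ½."""
    scores, labels, n_pos = _validate(scores, labels)
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class PermutationNull:
    n_perm: int
    values: np.ndarray
    mean: float
    sd: float  # sample sd (ddof=1)
    seed: int


def permutation_null(scores, labels, n_perm: int, seed: int) -> PermutationNull:
    """AUC distribution under uniformly random label shuffles.

    Vectorized over permutations: each replicate draws the positive-label
    positions uniformly and reuses the score ranks.
    """
    scores, labels, n_pos = _validate(scores, labels)
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    n = labels.size
    n_neg = n - n_pos
    ranks = stats.rankdata(scores)
    rng = np.random.default_rng(seed)
    values = np.empty(n_perm)
    chunk = 20000
    offset = n_pos * (n_pos + 1) / 2
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        # random permutation per row; first n_pos columns are the positives
        pos_idx = np.argsort(rng.random((m, n)), axis=1)[:, :n_pos]
        values[start : start + m] = (ranks[pos_idx].sum(axis=1) - offset) / (n_pos * n_neg)
    return PermutationNull(
        n_perm=n_perm,
        values=values,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        seed=seed,
    )


def auc_significance(observed_auc: float, null: PermutationNull) -> dict:
    """One-sided (upper-tail) significance of an observed AUC.

    Returns ``z``, the normal-approximation p-value, and the empirical
    permutation p-value ``(1 + #{null >= AUC}) / (1 + n_perm)``.
    """
    if np.unique(null.values).size < 2:
        raise ValueError("null distribution is degenerate (fewer than 2 distinct values)")
    z = (observed_auc - null.mean) / null.sd
    p_normal = float(stats.norm.sf(z))
    p_empirical = float((1 + (null.values >= observed_auc).sum()) / (1 + null.n_perm))
    return {
        "auc": float(observed_auc),
        "z": float(z),
        "p_normal": p_normal,
        "p_empirical": p_empirical,
        "null_mean": null.mean,
        "null_sd": null.sd,
        "n_perm": null.n_perm,
        "significant_05": p_empirical < 0.05,
    }
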