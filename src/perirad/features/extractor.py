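"""Feature extraction over masked images and whole cohorts.

``extract_features`` computes the configured battery for one volume/mask
pair (one phase, one compartment, one resolution).  ``extract_cohort``
orchestrates phases × compartments × resolutions × readers and returns one
feature table per reader with identical column keys.

Tables are ``pandas.DataFrame`` objects with subject ids as the index and a
6-level column MultiIndex (phase, compartment, resolution_mm, filter,
feature_class, feature_name).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..errors import EmptyMaskError
from ..geometry import build_tst, resample_mask, resample_volume
from ..grids import BinaryMask, Volume
from .config import KEY_FIELDS, ExtractionConfig
from .filters import derived_images
from .firstorder import firstorder_features
from .matrices import discretize
from .shape import shape_features
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

_TEXTURE_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "gldm": gldm_features,
    "ngtdm": ngtdm_features,
}

PHASES = ("early", "peak")
COMPARTMENTS = ("T", "TST")


def _crop_to_mask(values: np.ndarray, mask: np.ndarray, pad: int = 2):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return values[sl], mask[sl]


def extract_features(volume: Volume, mask: BinaryMask, config: ExtractionConfig) -> dict[tuple, float]:
    """Feature battery for one masked image.

    Returns ``{(filter, feature_class, feature_name): value}``.  Values that
    cannot be computed come back as NaN; cohort extraction drops those
    columns symmetrically across readers.
    """
    config.validate()
    volume.require_same_grid(mask)
    mask.require_nonempty()
    if mask.n_voxels < 2:
        raise EmptyMaskError("mask has fewer than 2 voxels; texture is undefined")

    vals, msk = _crop_to_mask(volume.values, mask.bool())
    out: dict[tuple, float] = {}

    if "shape" in config.feature_classes and "original" in config.filters:
        for name, v in shape_features(msk, volume.spacing).items():
            out[("original", "shape", name)] = v

    intensity_classes = [c for c in config.feature_classes if c != "shape"]
    if not intensity_classes:
        return out

    voxel_volume = volume.voxel_volume_mm3
    for img_name, img in derived_images(vals, volume.spacing, config).items():
        finite = np.all(np.isfinite(img[msk]))
        if finite:
            levels, n_levels = discretize(img, msk, config.bin_width)
        for cls in intensity_classes:
            if not finite:
                feats = None
            elif cls == "firstorder":
                feats = firstorder_features(img, msk, config.bin_width, voxel_volume)
            else:
                feats = _TEXTURE_FUNCS[cls](levels, msk, n_levels)
            if feats is None:  # keep the column count stable
                feats = {name: np.nan for name in _class_names(cls)}
            for name, v in feats.items():
                out[(img_name, cls, name)] = float(v) if np.isfinite(v) else np.nan
    return out


def _class_names(cls: str) -> tuple[str, ...]:
    from .firstorder import FIRSTORDER_NAMES
    from .texture import GLCM_NAMES, NGTDM_NAMES

    if cls == "firstorder":
        return FIRSTORDER_NAMES
    if cls == "glcm":
        return GLCM_NAMES
    if cls == "ngtdm":
        return NGTDM_NAMES
    # run-length-style families share a naming template; enumerate via a
    # 2x2 probe region
    probe = np.zeros((3, 3, 3))
    probe_mask = np.zeros((3, 3, 3), dtype=bool)
    probe_mask[:2, :2, 0] = True
    probe[probe_mask] = [1, 2, 3, 4]
    levels, n = discretize(probe, probe_mask, 1.0)
    return tuple(_TEXTURE_FUNCS[cls](levels, probe_mask, n).keys())


def extract_masked_image_set(
    early: Volume,
    peak: Volume,
    tumor_mask: BinaryMask,
    config: ExtractionConfig,
    tst_mask: BinaryMask | None = None,
    phases: tuple[str, ...] = PHASES,
    compartments: tuple[str, ...] = COMPARTMENTS,
) -> dict[tuple, float]:
    """Features for one subject and one reader across phases, compartments
    and resolutions; keys gain (phase, compartment, resolution) provenance."""
    if tst_mask is None and "TST" in compartments:
        tst_mask = build_tst(tumor_mask)
    volumes = {"early": early, "peak": peak}
    masks = {"T": tumor_mask, "TST": tst_mask}
    out: dict[tuple, float] = {}
    for res in config.resolutions_mm:
        rvols = {ph: resample_volume(volumes[ph], res) for ph in phases}
        rmasks = {cp: resample_mask(masks[cp], res) for cp in compartments}
        for ph in phases:
            for cp in compartments:
                feats = extract_features(rvols[ph], rmasks[cp], config)
                for (flt, cls, name), v in feats.items():
                    out[(ph, cp, float(res), flt, cls, name)] = v
    return out


def extract_cohort(
    cohort,
    config: ExtractionConfig,
    phases: tuple[str, ...] = PHASES,
    compartments: tuple[str, ...] = COMPARTMENTS,
    drop_nonfinite: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-reader feature tables for a cohort of synthetic patients.

    Non-finite columns are dropped symmetrically across both readers so the
    tables keep identical keys.
    """
    rows: dict[int, list[dict]] = {1: [], 2: []}
    ids = []
    for pat in cohort:
        ids.append(pat.id)
        for reader, mask in ((1, pat.reader1_mask), (2, pat.reader2_mask)):
            try:
                feats = extract_masked_image_set(
                    pat.early_volume, pat.peak_volume, mask, config,
                    phases=phases, compartments=compartments,
                )
            except EmptyMaskError as exc:
                raise EmptyMaskError(f"subject {pat.id}, reader {reader}: {exc}") from exc
            rows[reader].append(feats)

    tables = {}
    for reader in (1, 2):
        df = pd.DataFrame(rows[reader], index=ids)
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=KEY_FIELDS)
        tables[reader] = df
    t1, t2 = tables[1], tables[2]
    t2 = t2[t1.columns]  # identical key order

    if drop_nonfinite:
        bad = ~(np.isfinite(t1).all(axis=0) & np.isfinite(t2).all(axis=0))
        if bad.any():
            warnings.warn(f"dropping {int(bad.sum())} non-finite feature columns cohort-wide")
            t1 = t1.loc[:, ~bad]
            t2 = t2.loc[:, ~bad]
    return t1, t2


def zscore_columns(table: pd.DataFrame, fit_rows=None) -> tuple[pd.DataFrame, dict]:
    """Standardize columns to mean 0 / unit sample sd (ddof=1) learned on
    ``fit_rows`` and applied to all rows.

    Zero-variance columns (over the fit rows) are dropped with a warning.
    Returns the transformed table and the fitted parameters
    ``{"mean": Series, "sd": Series, "dropped": [keys]}``.
    """
    if fit_rows is None:
        fit_rows = table.index
    fit = table.loc[fit_rows]
    if len(fit) == 0:
        raise ValueError("fit_rows must be nonempty")
    mu = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=1)
    constant = sd == 0
    dropped = list(table.columns[constant])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance columns")
    keep = table.columns[~constant]
    out = (table[keep] - mu[keep]) / sd[keep]
    return out, {"mean": mu[keep], "sd": sd[keep], "dropped": dropped}


def table_to_csv(table: pd.DataFrame, path: str, reader: int) -> None:
    """Long-format CSV with the full 7-field provenance per value."""
    long = table.stack(list(range(table.columns.nlevels)), future_stack=True).rename("value").reset_index()
    long.insert(1, "reader", reader)
    long.columns = ["subject", "reader", *KEY_FIELDS, "value"]
    long.to_csv(path, index=False)


def table_from_csv(path: str) -> tuple[pd.DataFrame, int]:
    long = pd.read_csv(path)
    reader = int(long["reader"].iloc[0])
    wide = long.pivot(index="subject", columns=list(KEY_FIELDS), values="value")
    return wide, reader
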