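"""End-to-end orchestration: cohort → masks → features → repeatability →
nested CV → permutation significance → report.

The seven analysis combinations select (phase, compartment) column groups:

    a  early+peak / T+TST      e  peak / TST
    b  peak / T+TST            f  early / T
    c  early / T+TST           g  early / TST
    d  peak / T

Each combination is an independent nested-CV run on the consensus table
restricted to its columns.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .features import ExtractionConfig, extract_cohort, zscore_columns
from .features.extractor import table_to_csv
from .ncv import loo_ncv
from .pls import fit_pls, profile_top_features, top_beta_fraction
from .repeatability import consensus_table, mean_abs_correlation, repeatability_filter
from .significance import auc_significance, permutation_null, roc_auc
from .synthetic import RS_CUTOFF, CohortConfig, generate_cohort, read_cohort

__all__ = [
    "COMBINATIONS",
    "RunConfig",
    "parse_combination",
    "reduced_extraction_config",
    "reduced_cohort_config",
    "analyze_cohort",
    "run_pipeline",
]

COMBINATIONS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "a": (("early", "peak"), ("T", "TST")),
    "b": (("peak",), ("T", "TST")),
    "c": (("early",), ("T", "TST")),
    "d": (("peak",), ("T",)),
    "e": (("peak",), ("TST",)),
    "f": (("early",), ("T",)),
    "g": (("early",), ("TST",)),
}


def parse_combination(name: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Accepts a letter 'a'..'g' or a selector like 'early+peak/T+TST'."""
    if name in COMBINATIONS:
        return COMBINATIONS[name]
    if "/" in name:
        phase_part, comp_part = name.split("/", 1)
        phases = tuple(sorted(set(phase_part.split("+"))))
        comps = tuple(sorted(set(comp_part.split("+")), reverse=False))
        valid_ph = {"early", "peak"}
        valid_cp = {"T", "TST"}
        if set(phases) <= valid_ph and set(comps) <= valid_cp and phases and comps:
            return phases, tuple(sorted(comps))
    raise ConfigurationError(
        f"unknown combination {name!r}; valid names: {sorted(COMBINATIONS)} "
        "or selectors like 'early+peak/T+TST'"
    )


def reduced_extraction_config(**overrides) -> ExtractionConfig:
    """A light configuration (original filter, first-order + GLCM, native
    2 mm resolution) used for the calibration/recovery simulations."""
    kwargs = dict(
        filters=("original",),
        feature_classes=("firstorder", "glcm"),
        resolutions_mm=(2.0,),
        bin_width=25.0,
    )
    kwargs.update(overrides)
    return ExtractionConfig(**kwargs)


def reduced_cohort_config(seed: int, texture_effect: float, rim_effect: float, **overrides) -> CohortConfig:
    """A small, fast phantom cohort matching the study's size and prevalence
    (62 subjects, 15 positive)."""
    kwargs = dict(
        n_subjects=62,
        prevalence=15 / 62,
        grid_shape=(24, 24, 24),
        spacing_mm=(2.0, 2.0, 2.0),
        lesion_radius_mm=(6.0, 9.0),
        texture_effect=texture_effect,
        rim_effect=rim_effect,
        noise_sd=2.0,
        reader_perturb_mm=0.75,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_dir: str | None = None  # load NIfTI + labels CSV instead of simulating
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    repeatability_threshold: float = 0.95
    combination: str = "a"  # 'a'..'g', a selector, or 'all'
    k_grid: list[int] | None = None
    n_perm: int = 100_000
    perm_seed: int = 0
    zscore_mode: str = "fold"
    consensus_mode: str = "mean"
    selection_mode: str = "cohort"  # or 'fold' (selection inside outer folds)
    top_fraction: float = 0.05
    score_cutoff: int = RS_CUTOFF
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "cohort" in raw:
            kwargs["cohort"] = CohortConfig(**{k: tuple(v) if isinstance(v, list) else v
                                               for k, v in raw.pop("cohort").items()})
        if "extraction" in raw:
            kwargs["extraction"] = ExtractionConfig(**{k: tuple(v) if isinstance(v, list) else v
                                                       for k, v in raw.pop("extraction").items()})
        known = {f.name for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in known:
                raise ConfigurationError(f"unknown config field {key!r}")
            kwargs[key] = value
        return cls(**kwargs)


def _combination_columns(columns: pd.Index, phases, compartments) -> list:
    return [c for c in columns if c[0] in phases and c[1] in compartments]


def analyze_combination(
    consensus: pd.DataFrame,
    labels,
    phases,
    compartments,
    k_grid=None,
    n_perm: int = 10_000,
    perm_seed: int = 0,
    zscore_mode: str = "fold",
    column_selector=None,
    top_fraction: float = 0.05,
) -> dict:
    """Nested CV + significance + top-|β| profile for one column group."""
    cols = _combination_columns(consensus.columns, phases, compartments)
    if not cols:
        raise ConfigurationError(
            f"no features for phases={phases}, compartments={compartments}"
        )
    sub = consensus[cols]
    result = loo_ncv(sub, labels, k_grid=k_grid, zscore_mode=zscore_mode,
                     column_selector=column_selector)
    ok = np.isfinite(result.scores)
    auc = roc_auc(result.scores[ok], np.asarray(labels)[ok])
    null = permutation_null(result.scores[ok], np.asarray(labels)[ok], n_perm, perm_seed)
    sig = auc_significance(auc, null)

    # final all-subject fit at the modal fold k for the β-weight profile
    modal_k = int(pd.Series([k for k in result.fold_k if k > 0]).mode().iloc[0])
    z_table, _ = zscore_columns(sub)
    fit = fit_pls(z_table.to_numpy(float), np.asarray(labels, float),
                  min(modal_k, len(sub) - 1, z_table.shape[1]),
                  feature_keys=list(z_table.columns))
    top = top_beta_fraction(fit, top_fraction)
    profile = profile_top_features(top)

    return {
        "n_features": len(cols),
        "auc": sig["auc"],
        "z": sig["z"],
        "p_normal": sig["p_normal"],
        "p_empirical": sig["p_empirical"],
        "significant_05": sig["significant_05"],
        "null_mean": sig["null_mean"],
        "null_sd": sig["null_sd"],
        "null_q025": float(np.quantile(null.values, 0.025)),
        "null_q975": float(np.quantile(null.values, 0.975)),
        "n_perm": n_perm,
        "modal_k": modal_k,
        "fold_k": result.fold_k,
        "top_fraction_n": len(top),
        "top_profile": profile,
        "ncv": result,
        "fit": fit,
    }


def analyze_cohort(
    cohort,
    extraction: ExtractionConfig,
    labels=None,
    combination: str = "a",
    repeatability_threshold: float = 0.95,
    k_grid=None,
    n_perm: int = 10_000,
    perm_seed: int = 0,
    zscore_mode: str = "fold",
    consensus_mode: str = "mean",
    selection_mode: str = "cohort",
    top_fraction: float = 0.05,
) -> dict:
    """Feature extraction + repeatability selection + one combination's
    analysis, all in memory.  ``labels`` defaults to the cohort's own."""
    if labels is None:
        labels = [pat.label for pat in cohort]
    labels = np.asarray(labels, dtype=int)
    phases, compartments = parse_combination(combination)

    t1, t2 = extract_cohort(cohort, extraction, phases=phases, compartments=compartments)
    report = repeatability_filter(t1, t2, repeatability_threshold)
    consensus = consensus_table(t1, t2, report.selected, mode=consensus_mode)

    column_selector = None
    if selection_mode == "fold":
        def column_selector(train_rows, _t1=t1, _t2=t2):
            rep = repeatability_filter(_t1.loc[train_rows], _t2.loc[train_rows],
                                       repeatability_threshold)
            sel = [k for k in rep.selected if k in consensus.columns]
            return sel if sel else list(consensus.columns)
    elif selection_mode != "cohort":
        raise ConfigurationError(f"unknown selection_mode {selection_mode!r}")

    out = analyze_combination(
        consensus, labels, phases, compartments, k_grid=k_grid, n_perm=n_perm,
        perm_seed=perm_seed, zscore_mode=zscore_mode, column_selector=column_selector,
        top_fraction=top_fraction,
    )
    out["n_repeatable"] = len(report.selected)
    out["repeatability"] = report
    out["tables"] = (t1, t2)
    out["consensus"] = consensus
    return out


def _cache_key(config: RunConfig) -> str:
    import hashlib

    payload = repr((config.cohort, config.cohort_dir, config.extraction)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _load_cached_tables(outdir: str, key: str):
    from .features.extractor import table_from_csv

    marker = os.path.join(outdir, "features.cachekey")
    paths = [os.path.join(outdir, f"features_reader{r}.csv") for r in (1, 2)]
    if not (os.path.exists(marker) and all(os.path.exists(p) for p in paths)):
        return None, None
    with open(marker) as fh:
        if fh.read().strip() != key:
            return None, None
    t1, _ = table_from_csv(paths[0])
    t2, _ = table_from_csv(paths[1])
    return t1, t2[t1.columns].loc[t1.index]


def _store_cached_tables(outdir: str, key: str, t1, t2) -> None:
    os.makedirs(outdir, exist_ok=True)
    table_to_csv(t1, os.path.join(outdir, "features_reader1.csv"), reader=1)
    table_to_csv(t2, os.path.join(outdir, "features_reader2.csv"), reader=2)
    with open(os.path.join(outdir, "features.cachekey"), "w") as fh:
        fh.write(key)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every requested combination and write artifacts to ``outdir``.

    Returns the run report (also written as JSON when an output directory
    is configured).  A fixed seed reproduces the report exactly.
    """
    t_start = time.time()
    config.extraction.validate()
    names = list(COMBINATIONS) if config.combination == "all" else [config.combination]
    for name in names:
        parse_combination(name)

    if config.cohort_dir is not None:
        cohort = read_cohort(config.cohort_dir, score_cutoff=config.score_cutoff)
    else:
        config.cohort.validate()
        cohort = generate_cohort(config.cohort)
    labels = np.asarray([pat.label for pat in cohort])

    # extract once over the union of phases/compartments, then slice;
    # extraction dominates runtime, so cache the tables keyed on a content
    # hash of the cohort + extraction configuration
    t1 = t2 = None
    cache_key = _cache_key(config)
    if config.outdir:
        t1, t2 = _load_cached_tables(config.outdir, cache_key)
    if t1 is None:
        t1, t2 = extract_cohort(cohort, config.extraction)
        if config.outdir:
            _store_cached_tables(config.outdir, cache_key, t1, t2)
    rep = repeatability_filter(t1, t2, config.repeatability_threshold)
    consensus = consensus_table(t1, t2, rep.selected, mode=config.consensus_mode)

    report: dict = {
        "n_subjects": len(cohort),
        "n_positive": int(labels.sum()),
        "n_features_per_reader": int(t1.shape[1]),
        "n_repeatable": len(rep.selected),
        "mean_abs_correlation": mean_abs_correlation(consensus)
        if consensus.shape[1] >= 2 else None,
        "combinations": {},
        "stage_seconds": {},
    }
    report["stage_seconds"]["extract_select"] = round(time.time() - t_start, 3)

    for name in names:
        t0 = time.time()
        phases, compartments = parse_combination(name)
        column_selector = None
        if config.selection_mode == "fold":
            def column_selector(train_rows, _t1=t1, _t2=t2):
                r = repeatability_filter(_t1.loc[train_rows], _t2.loc[train_rows],
                                         config.repeatability_threshold)
                sel = [k for k in r.selected if k in consensus.columns]
                return sel if sel else list(consensus.columns)
        res = analyze_combination(
            consensus, labels, phases, compartments,
            k_grid=config.k_grid, n_perm=config.n_perm, perm_seed=config.perm_seed,
            zscore_mode=config.zscore_mode, column_selector=column_selector,
            top_fraction=config.top_fraction,
        )
        ncv_result = res.pop("ncv")
        res.pop("fit")
        res["combination"] = {"phases": list(phases), "compartments": list(compartments)}
        report["combinations"][name] = res
        report["stage_seconds"][f"ncv_{name}"] = round(time.time() - t0, 3)

        if config.outdir:
            os.makedirs(config.outdir, exist_ok=True)
            ncv_result.to_frame().to_csv(
                os.path.join(config.outdir, f"ncv_{name.replace('/', '_').replace('+', '')}.csv"),
                index=False,
            )

    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        if not os.path.exists(os.path.join(config.outdir, "features.cachekey")):
            _store_cached_tables(config.outdir, cache_key, t1, t2)
        rep.to_frame().to_csv(os.path.join(config.outdir, "repeatability.csv"))
        with open(os.path.join(config.outdir, "report.json"), "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report
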