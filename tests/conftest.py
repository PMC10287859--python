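import warnings

import numpy as np
import pytest

from perirad.features import ExtractionConfig
from perirad.grids import BinaryMask, Volume
from perirad.pipeline import analyze_cohort, reduced_cohort_config
from perirad.synthetic import CohortConfig, generate_cohort


def sphere_mask(radius_vox: int, spacing=(1.0, 1.0, 1.0), pad: int = 4) -> BinaryMask:
    n = 2 * (radius_vox + pad) + 1
    c = n // 2
    idx = np.indices((n, n, n))
    d2 = sum((idx[i] - c) ** 2 for i in range(3))
    return BinaryMask(values=(d2 <= radius_vox**2).astype(np.uint8), spacing=spacing)


@pytest.fixture(scope="session")
def small_cohort():
    """Four tiny subjects, fast enough for feature/table tests."""
    cfg = CohortConfig(
        n_subjects=4,
        prevalence=0.5,
        grid_shape=(24, 24, 16),
        spacing_mm=(1.5, 1.5, 3.0),
        lesion_radius_mm=(6.0, 8.0),
        seed=42,
    )
    return generate_cohort(cfg)


def reduced_extraction():
    return ExtractionConfig(
        filters=("original",), feature_classes=("firstorder",), resolutions_mm=(2.0,)
    )


def run_reduced_pipeline(seed: int, texture_effect: float, rim_effect: float,
                         n_perm: int = 10_000) -> dict:
    """One full reduced-scale pipeline run (generation → significance)."""
    cohort = generate_cohort(reduced_cohort_config(seed, texture_effect, rim_effect))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_cohort(
            cohort,
            reduced_extraction(),
            combination="a",
            n_perm=n_perm,
            perm_seed=seed,
            k_grid=[1, 2, 3],
        )


@pytest.fixture(scope="session")
def null_calibration():
    """Full pipeline on 200 zero-effect cohorts (shared across tests).

    Returns per-seed dicts with the observed AUC, the empirical p-value and
    the null central-95% interval.
    """
    out = []
    for seed in range(200):
        res = run_reduced_pipeline(seed, 0.0, 0.0)
        out.append(
            {
                "auc": res["auc"],
                "p_empirical": res["p_empirical"],
                "null_q025": res["null_q025"],
                "null_q975": res["null_q975"],
            }
        )
    return out
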