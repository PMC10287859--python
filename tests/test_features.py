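import numpy as np
import pandas as pd
import pytest

from perirad.errors import ConfigurationError, EmptyMaskError
from perirad.features import (
    ExtractionConfig,
    extract_cohort,
    extract_features,
    image_types,
    n_features_per_image,
    zscore_columns,
)
from perirad.features.config import CLASS_SIZES
from perirad.grids import BinaryMask, Volume


def _masked_image(values: np.ndarray, mask: np.ndarray, spacing=(1.0, 1.0, 1.0)):
    return (
        Volume(values=values.astype(float), spacing=spacing),
        BinaryMask(values=mask.astype(np.uint8), spacing=spacing),
    )


@pytest.fixture(scope="module")
def noisy_region():
    rng = np.random.default_rng(0)
    values = 100 + 30 * rng.random((12, 12, 12))
    mask = np.zeros((12, 12, 12), dtype=np.uint8)
    mask[2:10, 2:10, 2:10] = 1
    return _masked_image(values, mask)


# ------------------------------------------------------------ counts

def test_pinned_default_yields_1409_features(noisy_region):
    vol, mask = noisy_region
    feats = extract_features(vol, mask, ExtractionConfig())
    assert len(feats) == 1409


def test_count_decomposition():
    cfg = ExtractionConfig()
    intensity = sum(CLASS_SIZES[c] for c in cfg.feature_classes if c != "shape")
    assert intensity == 93
    assert CLASS_SIZES["shape"] == 14
    types = image_types(cfg)
    assert len(types) == 15  # original + 14 feature-yielding derived types
    assert n_features_per_image(cfg) == 15 * 93 + 14 == 1409


def test_enabling_log_and_lbp3d_changes_count():
    cfg = ExtractionConfig(log_sigmas_mm=(1.0, 2.0), enable_lbp3d=True)
    assert n_features_per_image(cfg) == 1409 + 3 * 93


def test_shape_only_config_gives_14(noisy_region):
    vol, mask = noisy_region
    cfg = ExtractionConfig(filters=("original",), feature_classes=("shape",))
    feats = extract_features(vol, mask, cfg)
    assert len(feats) == 14


def test_unknown_filter_rejected():
    with pytest.raises(ConfigurationError):
        ExtractionConfig(filters=("original", "sobel")).validate()


def test_tiny_mask_rejected(noisy_region):
    vol, _ = noisy_region
    single = np.zeros(vol.shape, dtype=np.uint8)
    single[5, 5, 5] = 1
    _, mask = _masked_image(vol.values, single)
    with pytest.raises(EmptyMaskError):
        extract_features(vol, mask, ExtractionConfig())


# ------------------------------------------------------------ analytic phantoms

def test_constant_region_degenerate_features():
    values = np.full((8, 8, 8), 42.0)
    mask = np.zeros((8, 8, 8), dtype=np.uint8)
    mask[2:6, 2:6, 2:6] = 1
    vol, msk = _masked_image(values, mask)
    cfg = ExtractionConfig(filters=("original",), feature_classes=("firstorder", "glcm"))
    feats = extract_features(vol, msk, cfg)
    assert feats[("original", "firstorder", "Variance")] == 0.0
    assert feats[("original", "firstorder", "Entropy")] == 0.0
    assert feats[("original", "glcm", "Contrast")] == 0.0


def test_checker_pattern_matches_bruteforce_cooccurrence():
    """4x4x1 two-level checkerboard: co-occurrence counts enumerated by hand."""
    values = np.zeros((4, 4, 1))
    for x in range(4):
        for y in range(4):
            values[x, y, 0] = 30.0 * ((x + y) % 2)
    mask = np.ones((4, 4, 1), dtype=np.uint8)
    vol, msk = _masked_image(values, mask)
    cfg = ExtractionConfig(filters=("original",), feature_classes=("firstorder", "glcm"),
                           bin_width=25.0)
    feats = extract_features(vol, msk, cfg)

    # first-order, by hand: 8 voxels at 0, 8 at 30
    assert feats[("original", "firstorder", "Mean")] == pytest.approx(15.0)
    assert feats[("original", "firstorder", "Entropy")] == pytest.approx(1.0)
    assert feats[("original", "firstorder", "Uniformity")] == pytest.approx(0.5)

    # brute-force symmetric co-occurrence over the 13 3-D directions
    levels = (values[:, :, 0] >= 25).astype(int) + 1
    counts = np.zeros((2, 2))
    dirs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) > (0, 0, 0)]
    for dx, dy, dz in dirs:
        if dz != 0:
            continue  # single-slice image
        for x in range(4):
            for y in range(4):
                u, v = x + dx, y + dy
                if 0 <= u < 4 and 0 <= v < 4:
                    a, b = levels[x, y] - 1, levels[u, v] - 1
                    counts[a, b] += 1
                    counts[b, a] += 1
    P = counts / counts.sum()
    i = np.arange(1, 3)
    I, J = np.meshgrid(i, i, indexing="ij")
    assert feats[("original", "glcm", "Contrast")] == pytest.approx(((I - J) ** 2 * P).sum())
    assert feats[("original", "glcm", "JointEnergy")] == pytest.approx((P**2).sum())
    assert feats[("original", "glcm", "MaximumProbability")] == pytest.approx(P.max())


def test_texture_invariant_under_intensity_shift(noisy_region):
    vol, mask = noisy_region
    cfg = ExtractionConfig(filters=("original",),
                           feature_classes=("glcm", "glrlm", "glszm", "gldm", "ngtdm"))
    feats0 = extract_features(vol, mask, cfg)
    shifted = Volume(values=vol.values + 137.0, spacing=vol.spacing)
    feats1 = extract_features(shifted, mask, cfg)
    for key in feats0:
        assert feats1[key] == pytest.approx(feats0[key], abs=1e-9), key


def test_firstorder_invariant_under_90deg_rotation(noisy_region):
    vol, mask = noisy_region
    cfg = ExtractionConfig(filters=("original",), feature_classes=("firstorder",))
    feats0 = extract_features(vol, mask, cfg)
    rot_v = Volume(values=np.rot90(vol.values, axes=(0, 1)).copy(), spacing=vol.spacing)
    rot_m = BinaryMask(values=np.rot90(mask.values, axes=(0, 1)).copy(), spacing=mask.spacing)
    feats1 = extract_features(rot_v, rot_m, cfg)
    for key in feats0:
        assert feats1[key] == pytest.approx(feats0[key], rel=1e-12), key


def test_extraction_deterministic(noisy_region):
    vol, mask = noisy_region
    cfg = ExtractionConfig()
    a = extract_features(vol, mask, cfg)
    b = extract_features(vol, mask, cfg)
    assert a == b


# ------------------------------------------------------------ cohort tables

def test_cohort_tables_share_keys_and_total(small_cohort):
    cfg = ExtractionConfig(filters=("original",),
                           feature_classes=("firstorder", "shape"),
                           resolutions_mm=(2.0, 3.0))
    t1, t2 = extract_cohort(small_cohort, cfg)
    assert t1.columns.equals(t2.columns)
    assert list(t1.index) == [p.id for p in small_cohort]
    # 2 phases x 2 compartments x 2 resolutions x 32 per image
    per_image = n_features_per_image(cfg)
    assert t1.shape[1] == 2 * 2 * 2 * per_image


def test_duplicate_reader_masks_give_identical_tables(small_cohort):
    import copy

    cohort = [copy.copy(p) for p in small_cohort[:2]]
    for p in cohort:
        p.reader2_mask = p.reader1_mask
    cfg = ExtractionConfig(filters=("original",), feature_classes=("firstorder",),
                           resolutions_mm=(2.0,))
    t1, t2 = extract_cohort(cohort, cfg)
    pd.testing.assert_frame_equal(t1, t2)


def test_table_csv_roundtrip(tmp_path, small_cohort):
    from perirad.features.extractor import table_from_csv, table_to_csv

    cfg = ExtractionConfig(filters=("original",), feature_classes=("firstorder",),
                           resolutions_mm=(3.0,))
    t1, _ = extract_cohort(small_cohort[:2], cfg)
    path = tmp_path / "reader1.csv"
    table_to_csv(t1, str(path), reader=1)
    back, reader = table_from_csv(str(path))
    assert reader == 1
    assert back.shape == t1.shape
    aligned = back.loc[t1.index, t1.columns]
    np.testing.assert_allclose(aligned.to_numpy(), t1.to_numpy())


# ------------------------------------------------------------ z-scoring

def test_zscore_pins_sample_sd_convention():
    table = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
    out, params = zscore_columns(table)
    np.testing.assert_allclose(out["f"].to_numpy(), [-1.0, 0.0, 1.0])
    assert params["sd"]["f"] == pytest.approx(1.0)


def test_zscore_idempotent():
    rng = np.random.default_rng(1)
    table = pd.DataFrame(rng.standard_normal((10, 3)))
    once, _ = zscore_columns(table)
    twice, _ = zscore_columns(once)
    pd.testing.assert_frame_equal(once, twice)


def test_zscore_drops_constant_column_with_warning():
    table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with pytest.warns(UserWarning, match="zero-variance"):
        out, params = zscore_columns(table)
    assert list(out.columns) == ["a"]
    assert params["dropped"] == ["b"]


def test_zscore_fit_rows_transform_applied_to_all():
    table = pd.DataFrame({"a": [0.0, 2.0, 4.0, 100.0]}, index=list("wxyz"))
    out, _ = zscore_columns(table, fit_rows=["w", "x", "y"])
    np.testing.assert_allclose(out.loc[["w", "x", "y"], "a"], [-1.0, 0.0, 1.0])
    assert out.loc["z", "a"] == pytest.approx((100.0 - 2.0) / 2.0)
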