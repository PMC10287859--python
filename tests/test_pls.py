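import numpy as np
import pytest

from perirad.pls import (
    PLSFit,
    fit_pls,
    pls1_path,
    predict,
    profile_top_features,
    top_beta_fraction,
)


def _random_problem(seed=0, n=20, p=5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = (rng.random(n) < 0.4).astype(float)
    y[0], y[1] = 0.0, 1.0  # both classes
    return X, y


# ------------------------------------------------------------ fitting

def test_y_equal_to_one_orthonormal_column_recovered_at_k1():
    rng = np.random.default_rng(1)
    raw = rng.standard_normal((16, 4))
    X, _ = np.linalg.qr(raw - raw.mean(0))  # orthonormal, mean-zero columns
    y = X[:, 2].copy()
    fit = fit_pls(X, y, k=1)
    preds = predict(fit, X)
    assert np.corrcoef(preds, y)[0, 1] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(4))
def test_full_rank_pls_equals_ols_oracle(seed):
    X, y = _random_problem(seed)
    Xc = X - X.mean(0)
    yc = y - y.mean()
    betas = pls1_path(Xc, yc, 5)
    # independent oracle: normal equations
    ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
    np.testing.assert_allclose(betas[-1], ols, atol=1e-10)


def test_orthonormal_columns_first_weight_aligned():
    n = 16
    raw = np.random.default_rng(2).standard_normal((n, 2))
    X, _ = np.linalg.qr(raw - raw.mean(0))  # orthonormal, mean-zero columns
    y = X[:, 0].copy()
    beta = pls1_path(X, y, 1)[0]
    # coefficient vector points along the first column (up to sign)
    assert abs(beta[0]) > 1e6 * abs(beta[1])


def test_training_rss_nonincreasing_in_k():
    X, y = _random_problem(3, n=25, p=8)
    Xc = X - X.mean(0)
    yc = y - y.mean()
    betas = pls1_path(Xc, yc, 8)
    rss = [((yc - Xc @ b) ** 2).sum() for b in betas]
    assert all(rss[i + 1] <= rss[i] + 1e-10 for i in range(len(rss) - 1))


def test_sign_equivariance():
    X, y = _random_problem(4)
    fit = fit_pls(X, y, k=3)
    X2 = X.copy()
    X2[:, 1] *= -1
    fit2 = fit_pls(X2, y, k=3)
    assert fit2.beta[1] == pytest.approx(-fit.beta[1])
    np.testing.assert_allclose(predict(fit2, X2), predict(fit, X), atol=1e-10)


def test_single_class_rejected():
    X, _ = _random_problem()
    with pytest.raises(ValueError):
        fit_pls(X, np.zeros(20), k=1)


def test_k_out_of_bounds_rejected():
    X, y = _random_problem()
    with pytest.raises(ValueError):
        fit_pls(X, y, k=0)
    with pytest.raises(ValueError):
        fit_pls(X, y, k=6)  # p = 5


# ------------------------------------------------------------ prediction

def test_predict_reproduces_training_scores():
    X, y = _random_problem(5)
    fit = fit_pls(X, y, k=2)
    np.testing.assert_allclose(predict(fit, X), fit.intercept + X @ fit.beta)


def test_predict_at_feature_means_returns_intercept():
    X, y = _random_problem(6)
    fit = fit_pls(X, y, k=2)
    scores = predict(fit, np.zeros((3, 5)))
    np.testing.assert_allclose(scores, fit.intercept)


def test_predict_hand_computed_dot_product():
    fit = PLSFit(n_components=1, beta=np.array([2.0, -1.0]), intercept=0.5,
                 feature_keys=["a", "b"])
    out = predict(fit, np.array([[3.0, 4.0]]))
    assert out[0] == pytest.approx(0.5 + 2.0 * 3.0 - 1.0 * 4.0)


def test_predict_column_mismatch_rejected():
    X, y = _random_problem(7)
    fit = fit_pls(X, y, k=1)
    with pytest.raises(ValueError):
        predict(fit, X[:, :3])


# ------------------------------------------------------------ top-|beta|

def test_top_fraction_940_gives_47():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((62, 940))
    y = (rng.random(62) < 0.24).astype(float)
    y[:2] = [0.0, 1.0]
    fit = fit_pls(X, y, k=5)
    assert len(top_beta_fraction(fit, 0.05)) == 47


def test_top_fraction_100_gives_5():
    fit = PLSFit(n_components=1, beta=np.arange(100, dtype=float), intercept=0.0,
                 feature_keys=[f"k{i:03d}" for i in range(100)])
    top = top_beta_fraction(fit, 0.05)
    assert len(top) == 5
    assert top == ["k099", "k098", "k097", "k096", "k095"]


def test_top_fraction_tie_break_lexicographic():
    keys = ["f", "a", "d", "b", "e", "c"]
    fit = PLSFit(n_components=1, beta=np.ones(6), intercept=0.0, feature_keys=keys)
    top = top_beta_fraction(fit, 0.5)
    assert top == ["a", "b", "c"]  # floor(0.5 * 6) = 3, ties by key order


def test_top_fraction_bad_fraction_rejected():
    fit = PLSFit(n_components=1, beta=np.ones(4), intercept=0.0, feature_keys=list("abcd"))
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            top_beta_fraction(fit, bad)


# ------------------------------------------------------------ profiles

def test_profile_counts_sum_to_total():
    keys = [
        ("peak", "TST", 1.0, "original", "glcm", "Contrast"),
        ("early", "T", 2.0, "wavelet-LLL", "firstorder", "Mean"),
        ("peak", "T", 1.0, "original", "shape", "Sphericity"),
    ]
    profile = profile_top_features(keys)
    assert profile["n"] == 3
    for breakdown in ("compartment", "phase", "resolution_mm", "class_group"):
        assert sum(profile[breakdown].values()) == 3


def test_profile_single_key():
    profile = profile_top_features([("peak", "TST", 1.0, "original", "glcm", "Idm")])
    assert profile["compartment"] == {"TST": 1}
    assert profile["phase"] == {"peak": 1}
    assert profile["resolution_mm"] == {1.0: 1}
    assert profile["class_group"] == {"texture": 1}


def test_profile_matches_groupby_oracle():
    rng = np.random.default_rng(9)
    phases = rng.choice(["early", "peak"], 30)
    comps = rng.choice(["T", "TST"], 30)
    keys = [
        (phases[i], comps[i], 1.0, "original", "glcm", f"feat{i}") for i in range(30)
    ]
    profile = profile_top_features(keys)
    assert profile["compartment"].get("T", 0) == int((comps == "T").sum())
    assert profile["phase"].get("peak", 0) == int((phases == "peak").sum())
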