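"""OLS and kernel-PLS models, cross-validation and splitting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tirnakit.regression_models import (
    ModelError,
    SplitSpec,
    fit_ols_log,
    fit_pls,
    loo_cv,
    r2_model_efficiency,
    split_train_validation,
)
from tirnakit.synthetic_fixtures import simulate_latent_problem


# ----------------------------------------------------------------- efficiency


def test_model_efficiency_values():
    assert r2_model_efficiency([1, 2, 3], [1, 2, 3]) == 1.0
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    assert r2_model_efficiency(obs, np.full(4, obs.mean())) == pytest.approx(0.0)
    assert r2_model_efficiency([0.0, 1.0], [2.0, 2.0]) == pytest.approx(-9.0)
    with pytest.raises(ModelError):
        r2_model_efficiency([1.0, 1.0], [1.0, 2.0])


# ------------------------------------------------------------------------ OLS


def test_ols_exact_recovery():
    x = np.linspace(-30, 0, 20)
    y = 10 ** (2.0 - 0.1 * x)
    fit = fit_ols_log(x, y)
    assert fit.beta0 == pytest.approx(2.0, abs=1e-9)
    assert fit.beta1 == pytest.approx(-0.1, abs=1e-9)
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)


def test_ols_constant_response():
    x = np.linspace(0, 1, 10)
    fit = fit_ols_log(x, np.full(10, 50.0))
    assert fit.beta1 == pytest.approx(0.0, abs=1e-12)
    assert fit.r2 == 0.0


def test_ols_rejects_nonpositive_y():
    with pytest.raises(ModelError, match="rows"):
        fit_ols_log(np.arange(5.0), np.array([1.0, 2.0, 0.0, 3.0, -1.0]))


def test_ols_confidence_band_contains_fit():
    rng = np.random.default_rng(0)
    x = rng.uniform(-20, 0, 36)
    y = 10 ** (1.5 + 0.05 * x + rng.normal(0, 0.1, 36))
    fit = fit_ols_log(x, y)
    band = fit.confidence_band(np.linspace(-20, 0, 50))
    assert (band["lower"] <= band["fit"] + 1e-12).all()
    assert (band["fit"] <= band["upper"] + 1e-12).all()


def test_ols_ci_coverage_of_slope():
    """95% CI covers the true slope at the nominal rate (3-sigma binomial
    band over 1,000 simulated replications, n = 36, known noise)."""
    rng = np.random.default_rng(12345)
    beta1_true = 0.05
    n, reps = 36, 1000
    hits = 0
    for _ in range(reps):
        x = rng.uniform(-30, 0, n)
        y = 10 ** (1.2 + beta1_true * x + rng.normal(0, 0.15, n))
        fit = fit_ols_log(x, y)
        lo, hi = fit.beta1_confint()
        hits += lo <= beta1_true <= hi
    p = 0.95
    se = np.sqrt(p * (1 - p) / reps)
    assert abs(hits / reps - p) <= 3 * se


# ------------------------------------------------------------------------ PLS


def _nipals_pls(X, y, A):
    """Independent NIPALS reference (deflates X and y explicitly)."""
    X0 = (X - X.mean(0)) / X.std(0, ddof=1)
    y0 = y - y.mean()
    n, k = X0.shape
    W = np.zeros((k, A))
    P = np.zeros((k, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    Xc, yc = X0.copy(), y0.copy()
    for a in range(A):
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        tt = t @ t
        p = Xc.T @ t / tt
        qa = yc @ t / tt
        Xc = Xc - np.outer(t, p)
        yc = yc - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
    coef = W @ np.linalg.inv(P.T @ W) @ q
    return coef, T


def test_pls_equals_ols_at_full_rank():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n, k = 30, 5
        X = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        fit = fit_pls(X, y, n_components=k)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(
            fit.predict(X), ols.predict(sm.add_constant(X)), atol=1e-8
        )


def test_pls_matches_nipals_reference():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 12))
    y = rng.normal(size=30)
    fit = fit_pls(X, y, n_components=4)
    coef_ref, T_ref = _nipals_pls(X, y, 4)
    assert np.allclose(fit.coef_scaled(4), coef_ref, atol=1e-8)
    assert np.allclose(fit.scores, T_ref, atol=1e-6)
    gram = fit.scores.T @ fit.scores
    assert np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)


def test_pls_single_orthogonal_predictor():
    # with orthogonal predictors a response carried by one column is
    # captured fully by the first component
    rng = np.random.default_rng(3)
    A = rng.normal(size=(20, 6))
    A -= A.mean(axis=0)  # columns orthogonal to the intercept
    X, _ = np.linalg.qr(A)  # mean-zero orthonormal columns
    assert np.allclose(X.mean(axis=0), 0, atol=1e-12)
    y = 3.0 * X[:, 2]
    fit = fit_pls(X, y, n_components=1)
    assert fit.y_variance_explained[0] == pytest.approx(100.0, abs=1e-8)


def test_pls_variance_explained_monotone():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(25, 8))
    y = rng.normal(size=25)
    fit = fit_pls(X, y, n_components=6)
    assert (np.diff(fit.x_variance_explained) >= -1e-9).all()
    assert fit.x_variance_explained[-1] <= 100.0 + 1e-9
    assert (np.diff(fit.y_variance_explained) >= -1e-9).all()


def test_pls_zero_variance_predictor_rejected():
    X = np.ones((10, 3))
    X[:, 1] = np.arange(10)
    with pytest.raises(ModelError, match="zero-variance"):
        fit_pls(X, np.arange(10.0), 1)


# --------------------------------------------------------------------- LOO-CV


def test_loo_cv_rank_one_problem():
    rng = np.random.default_rng(5)
    x1 = rng.normal(size=40)
    X = np.column_stack([x1, 0.5 * x1, -2.0 * x1])  # exactly rank 1
    y = 2.0 * x1
    rmsep, chosen = loo_cv(X, y, max_components=3)
    assert chosen == 1
    assert rmsep[0] < 1e-6


def test_loo_cv_pure_noise_prefers_few_components():
    rng = np.random.default_rng(6)
    wins = 0
    for rep in range(20):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        _, chosen = loo_cv(X, y, max_components=6)
        wins += chosen <= 2
    # with no signal, extra components mostly fit noise
    assert wins >= 12


def test_loo_cv_recovers_latent_dimension():
    hits = 0
    for seed in range(30):
        X, y = simulate_latent_problem(seed=seed)
        _, chosen = loo_cv(X, y, max_components=8)
        hits += chosen == 4
    assert hits >= 24  # >= 80%


# ---------------------------------------------------------------------- split


def test_split_ratios():
    rng = np.random.default_rng(7)
    y36 = pd.Series(rng.normal(size=36), index=[f"t{i}" for i in range(36)])
    train, val = split_train_validation(y36, SplitSpec(seed=1))
    assert len(train) == 30 and len(val) == 6
    y18 = y36.iloc[:18]
    train, val = split_train_validation(y18, SplitSpec(seed=1))
    assert len(train) == 15 and len(val) == 3


def test_split_stratified_and_deterministic():
    rng = np.random.default_rng(8)
    y = pd.Series(np.sort(rng.normal(size=36)), index=[f"t{i}" for i in range(36)])
    t1, v1 = split_train_validation(y, SplitSpec(seed=5))
    t2, v2 = split_train_validation(y, SplitSpec(seed=5))
    assert (t1, v1) == (t2, v2)
    # every tercile of the response distribution contributes validators
    ranks = y.rank(method="first")
    strata = [sum(1 for m in v1 if ranks[m] <= 12),
              sum(1 for m in v1 if 12 < ranks[m] <= 24),
              sum(1 for m in v1 if ranks[m] > 24)]
    assert strata == [2, 2, 2]
    assert set(v1).isdisjoint(t1)
    assert sorted(t1 + v1) == sorted(y.index)
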