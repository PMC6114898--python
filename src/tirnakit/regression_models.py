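"""Sequence-function regression: log-linear OLS and kernel PLS.

Two models link tiRNA features to measured relative protein expression Y:

* a one-predictor log-linear model, log10(Y) = b0 + b1 * FAB + eps, fitted
  by ordinary least squares on the raw (unprocessed) FAB values, with a
  normal-theory 95% confidence band;

* a kernel partial-least-squares model on all 12 features, using the
  covariance-recursion ("improved kernel") algorithm of Dayal & MacGregor:
  only X'y is deflated, scores/loadings are recovered from the covariance
  matrices.  Predictors are centred and scaled by the sample standard
  deviation; the response is centred but not scaled.

Model selection uses leave-one-out cross-validation (scaling recomputed
inside each fold to avoid leakage); the component count minimising RMSEP is
chosen, ties broken toward parsimony.  Train/validation splitting is
response-stratified: records ordered by mean response, cut into 3 strata,
validation members drawn per stratum to a 5:1 ratio.

Goodness of fit is reported as model efficiency (Nash-Sutcliffe form)

    R2 = 1 - sum (o - p)^2 / sum (o - mean(o))^2

which can be negative; the squared-correlation R2 is reported alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("tirnakit")


class ModelError(ValueError):
    pass


# --------------------------------------------------------------------------
# model efficiency
# --------------------------------------------------------------------------


def r2_model_efficiency(observed, predicted) -> float:
    """1 - SSE / SStot (Nash-Sutcliffe-type efficiency; may be negative)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size < 2:
        raise ModelError("need at least 2 observations")
    sstot = float(((o - o.mean()) ** 2).sum())
    if sstot == 0.0:
        raise ModelError("observed values are constant; efficiency undefined")
    return 1.0 - float(((o - p) ** 2).sum()) / sstot


# --------------------------------------------------------------------------
# OLS log-linear model
# --------------------------------------------------------------------------


@dataclass
class OlsFit:
    beta0: float
    beta1: float
    residual_variance: float
    r2: float
    n: int
    _results: object = field(repr=False, default=None)

    def predict_log10(self, x) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(x, dtype=float)

    def predict(self, x) -> np.ndarray:
        return 10.0 ** self.predict_log10(x)

    def confidence_band(self, x, alpha: float = 0.05) -> pd.DataFrame:
        """Normal-theory CI band for the mean of log10(Y) over predictor
        values x (plot-ready: columns fit, lower, upper)."""
        x = np.asarray(x, dtype=float)
        exog = sm.add_constant(x)
        pred = self._results.get_prediction(exog)
        frame = pred.summary_frame(alpha=alpha)
        return pd.DataFrame(
            {
                "x": x,
                "fit": frame["mean"].to_numpy(),
                "lower": frame["mean_ci_lower"].to_numpy(),
                "upper": frame["mean_ci_upper"].to_numpy(),
            }
        )

    def beta1_confint(self, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = self._results.conf_int(alpha=alpha)[1]
        return float(lo), float(hi)

    @property
    def beta1_pvalue(self) -> float:
        return float(self._results.pvalues[1])


def fit_ols_log(fab, y_percent) -> OlsFit:
    """OLS of log10(relative expression) on raw FAB values."""
    x = np.asarray(fab, dtype=float)
    y = np.asarray(y_percent, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ModelError("fab and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ModelError("need at least 3 observations")
    bad = np.where(y <= 0)[0]
    if bad.size:
        raise ModelError(f"log10 undefined for non-positive responses at rows {bad.tolist()}")
    ly = np.log10(y)
    res = sm.OLS(ly, sm.add_constant(x)).fit()
    pred = res.predict(sm.add_constant(x))
    if np.allclose(ly, ly[0]):
        r2 = 0.0
    else:
        r2 = r2_model_efficiency(ly, pred)
    return OlsFit(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        residual_variance=float(res.mse_resid) if x.size > 2 else 0.0,
        r2=r2,
        n=int(x.size),
        _results=res,
    )


# --------------------------------------------------------------------------
# kernel PLS (Dayal & MacGregor covariance recursion)
# --------------------------------------------------------------------------


@dataclass
class PlsFit:
    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray  # sample sd divisors
    y_mean: float
    weights: np.ndarray      # W (k x A), unit-norm X'y directions
    rotations: np.ndarray    # R (k x A): T = X0 @ R
    loadings: np.ndarray     # P (k x A)
    y_loadings: np.ndarray   # q (A,)
    scores: np.ndarray       # T (n x A) on the training data
    coefficients: np.ndarray  # (k x A): column a = coefs using 1..a+1 comps (scaled X)
    x_variance_explained: np.ndarray  # cumulative %
    y_variance_explained: np.ndarray  # cumulative %
    feature_names: list[str] | None = None

    def coef_scaled(self, n_components: int | None = None) -> np.ndarray:
        a = (n_components or self.n_components) - 1
        return self.coefficients[:, a]

    def coef_raw(self, n_components: int | None = None) -> tuple[np.ndarray, float]:
        """(slope per raw feature unit, intercept) on the original scales."""
        b = self.coef_scaled(n_components) / self.x_scale
        intercept = self.y_mean - float(self.x_mean @ b)
        return b, intercept

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        b, intercept = self.coef_raw(n_components)
        return X @ b + intercept

    def to_json(self, path=None) -> str:
        payload = {
            "n_components": self.n_components,
            "feature_names": self.feature_names,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "coefficients_scaled": self.coef_scaled().tolist(),
            "x_variance_explained": self.x_variance_explained.tolist(),
            "y_variance_explained": self.y_variance_explained.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _center_scale(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = np.where(scale == 0)[0]
    if zero.size:
        raise ModelError(f"zero-variance predictor column(s) at {zero.tolist()}")
    return (X - mean) / scale, mean, scale


def fit_pls(
    x,
    y,
    n_components: int,
    feature_names: list[str] | None = None,
    strict: bool = True,
) -> PlsFit:
    """Kernel PLS with the Dayal-MacGregor covariance recursion.

    Works entirely from X'X and X'y; only X'y is deflated.  Predictors are
    centred and scaled by sample sd, the response is centred only.
    """
    X = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if yv.size != n:
        raise ModelError("x and y sizes disagree")
    if n < 2:
        raise ModelError("need at least 2 observations")
    X0, x_mean, x_scale = _center_scale(X)
    y_mean = float(yv.mean())
    y0 = yv - y_mean
    A = int(n_components)
    if not (1 <= A <= min(n - 1, k)):
        raise ModelError(f"n_components must be in [1, {min(n - 1, k)}]")
    XtX = X0.T @ X0
    Xty = X0.T @ y0
    W = np.zeros((k, A))
    R = np.zeros((k, A))
    P = np.zeros((k, A))
    q = np.zeros(A)
    tt = np.zeros(A)
    realised = A
    for a in range(A):
        w = Xty.copy()
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            # the response is fully deflated: no further components exist
            if strict:
                raise ModelError(
                    f"X'y deflated to zero at component {a + 1}; reduce n_components"
                )
            realised = a
            break
        w /= norm
        r = w.copy()
        for j in range(a):
            r -= float(P[:, j] @ w) * R[:, j]
        ttj = float(r @ XtX @ r)
        if ttj <= 1e-12:
            if strict:
                raise ModelError(f"degenerate score variance at component {a + 1}")
            realised = a
            break
        P[:, a] = (XtX @ r) / ttj
        q[a] = float(r @ Xty) / ttj
        Xty = Xty - ttj * q[a] * P[:, a]
        W[:, a] = w
        R[:, a] = r
        tt[a] = ttj
    if realised < A:
        if realised == 0:
            raise ModelError("no usable PLS component (X'y vanishes)")
        A = realised
        W, R, P, q, tt = W[:, :A], R[:, :A], P[:, :A], q[:A], tt[:A]
    coeffs = np.cumsum(R * q, axis=1)  # column a: R[:, :a+1] @ q[:a+1]
    T = X0 @ R
    ssx = float((X0**2).sum())
    ssy = float((y0**2).sum())
    x_var = 100.0 * np.cumsum(tt * (P**2).sum(axis=0)) / ssx
    y_var = 100.0 * np.cumsum(tt * q**2) / ssy if ssy > 0 else np.zeros(A)
    return PlsFit(
        n_components=A,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        weights=W,
        rotations=R,
        loadings=P,
        y_loadings=q,
        scores=T,
        coefficients=coeffs,
        x_variance_explained=x_var,
        y_variance_explained=y_var,
        feature_names=list(feature_names) if feature_names else None,
    )


def loo_cv(x, y, max_components: int) -> tuple[np.ndarray, int]:
    """Leave-one-out RMSEP for 1..max_components and the chosen count.

    Centring/scaling is recomputed inside every fold.  The chosen component
    count is the global RMSEP minimiser; ties go to fewer components.
    """
    X = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if n < 3:
        raise ModelError("need at least 3 observations for LOO-CV")
    a_max = min(max_components, n - 2, k)
    sq_err = np.zeros((n, a_max))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fit = fit_pls(X[mask], yv[mask], n_components=a_max, strict=False)
        for a in range(1, a_max + 1):
            # when the fold supports fewer components, later counts reuse
            # the largest realised model (adding none changes nothing)
            pred = fit.predict(X[i : i + 1], n_components=min(a, fit.n_components))[0]
            sq_err[i, a - 1] = (yv[i] - pred) ** 2
    rmsep = np.sqrt(sq_err.mean(axis=0))
    chosen = int(np.argmin(rmsep)) + 1  # argmin takes the first (fewest) on ties
    return rmsep, chosen


# --------------------------------------------------------------------------
# stratified train/validation split
# --------------------------------------------------------------------------


@dataclass
class SplitSpec:
    ratio: tuple[int, int] = (5, 1)
    n_strata: int = 3
    seed: int = 0


def split_train_validation(
    responses: pd.Series, spec: SplitSpec | None = None
) -> tuple[list, list]:
    """(train ids, validation ids) by response-stratified sampling.

    Records are ordered by mean response and cut into ``n_strata``
    equal-size strata (remainder to the lower strata); validation members
    are drawn uniformly per stratum to reach the train:validation ratio.
    """
    spec = spec or SplitSpec()
    n = len(responses)
    if n < 2 * spec.n_strata:
        raise ModelError("too few records to stratify")
    train_w, val_w = spec.ratio
    n_val = (n * val_w) // (train_w + val_w)
    if n_val < 1:
        raise ModelError("split ratio yields an empty validation set")
    order = responses.sort_values(kind="mergesort").index.to_list()
    base, rem = divmod(n, spec.n_strata)
    sizes = [base + (1 if s < rem else 0) for s in range(spec.n_strata)]
    strata: list[list] = []
    pos = 0
    for size in sizes:
        strata.append(order[pos : pos + size])
        pos += size
    per, extra = divmod(n_val, spec.n_strata)
    picks = [per + (1 if s < extra else 0) for s in range(spec.n_strata)]
    rng = np.random.default_rng(spec.seed)
    validation: list = []
    for stratum, k in zip(strata, picks):
        k = min(k, len(stratum))
        chosen = rng.choice(len(stratum), size=k, replace=False)
        validation.extend(stratum[int(c)] for c in sorted(chosen))
    val_set = set(validation)
    train = [i for i in responses.index if i not in val_set]
    return train, validation
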