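"""Environment-based trait prediction.

Four methods map standardized environmental predictors to a standardized
trait: linear regression with backward AIC selection (LM), elastic net (EN),
random forest regression (RF) and canonical correlation analysis (CCA).
EN and RF operate on an expanded feature set (raw columns, their squares
and pairwise products, 2p + p(p-1)/2 columns in total); LM and CCA use the
raw columns only, since the expansion would exceed typical sample sizes.

All models are fit without an intercept (data standardized on the fitting
set), are deterministic given a seed, and can be applied to accessions that
carry only environmental data.  A prediction whose sample SD falls below a
tolerance is flagged constant; downstream bivariate analyses must then fall
back to the univariate results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np

__all__ = [
    "FeatureMatrix",
    "PredictionModel",
    "PredictedTrait",
    "expand_features",
    "fit_lm_backward_aic",
    "fit_elastic_net",
    "fit_random_forest",
    "fit_cca",
    "fit_prediction",
    "apply_prediction",
    "is_constant_prediction",
    "save_model",
    "load_model",
]

CONSTANT_TOL = 1e-10


@dataclass
class FeatureMatrix:
    """Feature columns with provenance (raw / squared / interaction)."""

    names: list[str]
    provenance: list[str]
    values: np.ndarray
    mean: np.ndarray | None = None  # standardization parameters (fit set)
    sd: np.ndarray | None = None


def expand_features(
    X_raw: np.ndarray,
    names: list[str] | None = None,
    include_interactions: bool = True,
    standardize: bool = True,
    mean: np.ndarray | None = None,
    sd: np.ndarray | None = None,
) -> FeatureMatrix:
    """Expand p raw columns to raw + squares + pairwise products.

    With ``include_interactions`` the column count is 2p + p(p-1)/2;
    otherwise the raw columns are returned unchanged.  Expanded columns are
    re-standardized on the fitting set unless precomputed (mean, sd) are
    replayed (application to new accessions).
    """
    X = np.asarray(X_raw, dtype=float)
    p = X.shape[1]
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    if len(set(names)) != p:
        raise ValueError("duplicate raw column names")
    if not include_interactions:
        return FeatureMatrix(list(names), ["raw"] * p, X.copy())
    cols = [X]
    out_names = list(names)
    prov = ["raw"] * p
    cols.append(X**2)
    out_names += [f"{c}^2" for c in names]
    prov += ["squared"] * p
    inter = []
    for j in range(p):
        for jp in range(j + 1, p):
            inter.append(X[:, j] * X[:, jp])
            out_names.append(f"{names[j]}*{names[jp]}")
            prov.append("interaction")
    if inter:
        cols.append(np.column_stack(inter))
    V = np.column_stack(cols)
    if standardize:
        if mean is None:
            mean = V.mean(axis=0)
            sd = V.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
        V = (V - mean) / sd
        return FeatureMatrix(out_names, prov, V, mean, sd)
    return FeatureMatrix(out_names, prov, V)


@dataclass
class PredictionModel:
    """A fitted environment -> trait map, replayable on new accessions."""

    method: str  # LM | EN | RF | CCA
    raw_names: list[str]
    include_interactions: bool
    params: dict[str, Any] = field(default_factory=dict)
    estimator: Any = None  # RF ensemble when method == "RF"
    expansion_mean: np.ndarray | None = None
    expansion_sd: np.ndarray | None = None
    fit_ids: list[str] | None = None
    fitted_values: np.ndarray | None = None
    fit_range: tuple[float, float] | None = None
    fit_corr: float = np.nan

    def predict_raw(self, X_raw: np.ndarray) -> np.ndarray:
        X = np.asarray(X_raw, dtype=float)
        if X.shape[1] != len(self.raw_names):
            raise ValueError("raw environmental column count mismatch")
        fm = expand_features(
            X, self.raw_names, include_interactions=self.include_interactions,
            mean=self.expansion_mean, sd=self.expansion_sd,
        )
        if self.method in ("LM", "CCA", "EN"):
            return fm.values @ self.params["coef"] - self.params.get("offset", 0.0)
        if self.method == "RF":
            return self.estimator.predict(fm.values)
        raise ValueError(f"unknown method {self.method!r}")


@dataclass
class PredictedTrait:
    """Predictions for a set of accessions plus degeneracy bookkeeping."""

    accession_ids: list[str]
    y_hat: np.ndarray
    constant: bool
    fit_corr: float = np.nan
    in_range: np.ndarray | None = None

    @property
    def n_excluded(self) -> int:
        return 0 if self.in_range is None else int((~self.in_range).sum())


def is_constant_prediction(y_hat: np.ndarray, tol: float = CONSTANT_TOL) -> bool:
    """True iff the sample SD of the prediction is below ``tol``."""
    return bool(np.std(np.asarray(y_hat, dtype=float)) < tol)


# ---------------------------------------------------------------------------
# LM: backward selection by AIC


def aic_no_intercept(rss: float, n: int, k: int) -> float:
    """AIC = n log(RSS/n) + 2k for a Gaussian linear model (no intercept).

    For the empty model RSS = sum(y^2).  Additive constants are dropped, as
    they cancel in comparisons.
    """
    return n * np.log(rss / n) + 2 * k


def _rss(X, y):
    if X.shape[1] == 0:
        return float(y @ y)
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0])
    r = y - X @ coef
    return float(r @ r)


def fit_lm_backward_aic(y: np.ndarray, X: np.ndarray, names: list[str] | None = None) -> PredictionModel:
    """Backward AIC selection from the full no-intercept linear model.

    At each step the single-variable deletion with the lowest AIC is taken
    while it improves on the current model; the empty model is a legal
    endpoint and yields an all-zero (constant-flagged) prediction.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    if n <= p:
        raise ValueError("n <= p: backward selection needs n > p; use EN or RF")
    active = list(range(p))
    cur_aic = aic_no_intercept(_rss(X[:, active], y), n, len(active))
    while active:
        cand = []
        for j in active:
            rest = [a for a in active if a != j]
            cand.append((aic_no_intercept(_rss(X[:, rest], y), n, len(rest)), j))
        best_aic, best_j = min(cand)
        if best_aic < cur_aic:
            active.remove(best_j)
            cur_aic = best_aic
        else:
            break
    coef = np.zeros(p)
    if active:
        coef[active], *_ = np.linalg.lstsq(X[:, active], y, rcond=None)
    fitted = X @ coef
    return _finish_linear("LM", coef, names, False, y, fitted,
                          extra={"selected": [names[j] for j in active], "aic": cur_aic})


def _finish_linear(method, coef, names, include_interactions, y, fitted, extra=None,
                   mean=None, sd=None):
    const = is_constant_prediction(fitted)
    corr = np.nan
    if not const and np.std(y) > 0:
        corr = float(np.corrcoef(fitted, y)[0, 1])
    params = {"coef": np.asarray(coef, dtype=float)}
    if extra:
        params.update(extra)
    return PredictionModel(
        method=method, raw_names=list(names), include_interactions=include_interactions,
        params=params, expansion_mean=mean, expansion_sd=sd,
        fitted_values=fitted, fit_range=(float(fitted.min()), float(fitted.max())),
        fit_corr=corr,
    )


# ---------------------------------------------------------------------------
# EN: elastic net with alpha = 0.5, lambda by 10-fold CV


def fit_elastic_net(
    y: np.ndarray, X_expanded: FeatureMatrix, seed: int = 0,
    l1_ratio: float = 0.5, n_lambdas: int = 100, n_folds: int = 10,
) -> PredictionModel:
    """Elastic net at fixed L1/L2 mixing 0.5; penalty chosen as the CV-minimum
    over a log-spaced path, fold assignment seeded, no intercept."""
    from sklearn.linear_model import ElasticNetCV
    from sklearn.model_selection import KFold

    y = np.asarray(y, dtype=float)
    V = X_expanded.values
    n = len(y)
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} observations for {n_folds}-fold CV")
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
    # path floor 0.01*alpha_max matches the usual n < p convention
    model = ElasticNetCV(
        l1_ratio=l1_ratio, alphas=n_lambdas, eps=1e-2, cv=cv, fit_intercept=False,
        max_iter=1000, tol=1e-4,
    )
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(V, y)
    coef = model.coef_
    fitted = V @ coef
    out = _finish_linear(
        "EN", coef, X_expanded.names, True, y, fitted,
        extra={"lambda": float(model.alpha_), "l1_ratio": l1_ratio},
        mean=X_expanded.mean, sd=X_expanded.sd,
    )
    out.raw_names = _raw_names_of(X_expanded)
    return out


def _raw_names_of(fm: FeatureMatrix) -> list[str]:
    return [n for n, p in zip(fm.names, fm.provenance) if p == "raw"]


def elastic_net_objective(beta, y, V, lam, l1_ratio=0.5):
    """The penalized least-squares objective minimized by the EN fit
    (scikit-learn scaling: RSS/(2n) + lam * penalty)."""
    n = len(y)
    r = y - V @ beta
    pen = lam * (l1_ratio * np.abs(beta).sum() + 0.5 * (1 - l1_ratio) * (beta**2).sum())
    return float(r @ r / (2 * n) + pen)


# ---------------------------------------------------------------------------
# RF: random forest regression


def fit_random_forest(
    y: np.ndarray, X_expanded: FeatureMatrix, n_trees: int = 500, seed: int = 0,
    oob: bool = False,
) -> PredictionModel:
    """Bootstrap ensemble of regression trees; prediction = ensemble mean.

    One third of the features are candidates at each split (the regression
    convention); trees are grown to full depth.
    """
    from sklearn.ensemble import RandomForestRegressor

    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    y = np.asarray(y, dtype=float)
    V = X_expanded.values
    # p/3 candidate features per split and leaf size 5: the standard
    # regression-forest configuration
    rf = RandomForestRegressor(
        n_estimators=int(n_trees), max_features=1.0 / 3.0, min_samples_leaf=5,
        random_state=int(seed) % (2**31), oob_score=oob, bootstrap=True, n_jobs=1,
    )
    rf.fit(V, y)
    fitted = rf.predict(V)
    const = is_constant_prediction(fitted)
    corr = float(np.corrcoef(fitted, y)[0, 1]) if not const and np.std(y) > 0 else np.nan
    return PredictionModel(
        method="RF", raw_names=_raw_names_of(X_expanded),
        include_interactions=True,
        params={
            "n_trees": int(n_trees),
            "importances": rf.feature_importances_,
            "oob_r2": float(rf.oob_score_) if oob else np.nan,
            "feature_names": list(X_expanded.names),
        },
        estimator=rf, expansion_mean=X_expanded.mean, expansion_sd=X_expanded.sd,
        fitted_values=fitted, fit_range=(float(fitted.min()), float(fitted.max())),
        fit_corr=corr,
    )


# ---------------------------------------------------------------------------
# CCA


def fit_cca(Y_multi: np.ndarray, X_raw: np.ndarray, names: list[str] | None = None) -> PredictionModel:
    """Classical canonical correlation analysis via SVD.

    Returns the environment-side linear combination of the first canonical
    pair, oriented to correlate positively with the first trait column.
    With a single trait the canonical variate is proportional to the OLS
    fitted values of the no-intercept regression of y on X.
    """
    Y = np.asarray(Y_multi, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = np.asarray(X_raw, dtype=float)
    n, p = X.shape
    t = Y.shape[1]
    if n <= p + t:
        raise ValueError("need n > p + t for CCA")
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Qx, Rx = np.linalg.qr(Xc)
    Qy, Ry = np.linalg.qr(Yc)
    if np.linalg.matrix_rank(Rx) < p:
        raise ValueError("rank-deficient X: drop collinear environmental columns")
    Uu, s, Vt = np.linalg.svd(Qx.T @ Qy)
    corrs = np.clip(s, 0.0, 1.0)
    a = np.linalg.solve(Rx, Uu[:, 0])  # env-side weights
    variate = Xc @ a
    # sign: positive correlation with the first observed trait
    c0 = np.corrcoef(variate, Y[:, 0])[0, 1]
    if c0 < 0:
        a, variate = -a, -variate
    # centering replayed on new rows as a stored offset
    return _finish_linear(
        "CCA", a, names, False, Y[:, 0], variate,
        extra={"canonical_correlations": corrs, "offset": float(X.mean(axis=0) @ a)},
    )


# ---------------------------------------------------------------------------
# unified front end


def fit_prediction(
    method: str, y: np.ndarray, X_raw: np.ndarray, seed: int = 0,
    names: list[str] | None = None, n_trees: int = 500,
    Y_multi: np.ndarray | None = None,
) -> PredictionModel:
    """Fit any of the four methods on standardized (y, X_raw).

    ``method`` in {'lm','en','rf','cca'}.  EN and RF receive the expanded
    feature set; LM and CCA the raw columns.  ``Y_multi`` optionally supplies
    several trait columns to CCA.
    """
    m = method.lower()
    X = np.asarray(X_raw, dtype=float)
    if m == "lm":
        return fit_lm_backward_aic(y, X, names)
    if m == "cca":
        Y = Y_multi if Y_multi is not None else np.asarray(y, dtype=float)
        return fit_cca(Y, X, names)
    fm = expand_features(X, names, include_interactions=True)
    if m == "en":
        return fit_elastic_net(y, fm, seed=seed)
    if m == "rf":
        return fit_random_forest(y, fm, n_trees=n_trees, seed=seed)
    raise ValueError(f"unknown prediction method {method!r}")


def apply_prediction(
    model: PredictionModel,
    X_raw_new: np.ndarray,
    accession_ids: list[str] | None = None,
    range_filter: bool = False,
) -> PredictedTrait:
    """Apply a fitted model to new accessions (environmental columns only).

    Scaling and feature expansion are replayed from the stored parameters.
    With ``range_filter`` accessions whose prediction falls outside the
    fitting-set range are marked out-of-range (``in_range`` mask).
    """
    X = np.asarray(X_raw_new, dtype=float)
    if accession_ids is None:
        accession_ids = [str(i) for i in range(X.shape[0])]
    y_hat = model.predict_raw(X)
    in_range = None
    if range_filter and model.fit_range is not None:
        lo, hi = model.fit_range
        in_range = (y_hat >= lo) & (y_hat <= hi)
    return PredictedTrait(
        accession_ids=list(accession_ids), y_hat=y_hat,
        constant=is_constant_prediction(y_hat), fit_corr=model.fit_corr,
        in_range=in_range,
    )


def save_model(model: PredictionModel, path: str) -> None:
    joblib.dump(model, path)


def load_model(path: str) -> PredictionModel:
    return joblib.load(path)
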