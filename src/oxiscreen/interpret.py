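"""Interpretation: spline nonlinearity tests, Shapley attribution, subgroups.

Restricted cubic splines follow the standard truncated-power construction
(linear in the tails); the nonlinearity test is a likelihood-ratio test of
the df-dimensional spline logistic model against the 1-df linear one.

Shapley attributions are computed by exhaustive coalition enumeration with a
marginal (background-averaged) value function. With at most eight features
this is exact for every model family, and per-sample additivity
``base_value + Σ contributions = model output`` holds to float precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from math import factorial
from scipy.special import expit
from scipy.stats import chi2

from oxiscreen.errors import ContractError, FitError
from oxiscreen.model_dev import SubsetResult, TrainedModel, subset_search

OLDER_AGE_CUTOFF = 60  # years; the older stratum is age >= cutoff


# --------------------------------------------------------------------------
# restricted cubic splines

def rcs_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Knots at equally spaced quantiles between 0.05 and 0.95."""
    qs = np.linspace(0.05, 0.95, n_knots)
    knots = np.quantile(np.asarray(x, dtype=np.float64), qs)
    if len(np.unique(knots)) != n_knots:
        raise FitError("tied knots: predictor has too few distinct values")
    return knots


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power restricted-cubic-spline basis: k knots → k-1 columns.

    First column is x itself; the k-2 nonlinear columns are constrained to be
    linear beyond the boundary knots and are scaled by (t_k − t_1)^2 for
    conditioning.
    """
    x = np.asarray(x, dtype=np.float64)
    t = np.asarray(knots, dtype=np.float64)
    k = len(t)
    if k < 3:
        raise ContractError("restricted cubic splines need at least 3 knots")
    norm = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


@dataclass
class RcsFit:
    predictor_name: str
    knots: np.ndarray
    coefficients: np.ndarray
    loglik_spline: float
    loglik_linear: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    curve: pd.DataFrame  # value, probability, lower, upper


def _fit_logit(X: np.ndarray, y: np.ndarray):
    try:
        with warnings.catch_warnings():
            # near-separation raises optimizer noise; a finite fit is still usable
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # separation, singular design, ...
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError("logistic fit diverged (non-finite coefficients)")
    return res


def rcs_logistic(x: np.ndarray, y: np.ndarray, df: int = 5,
                 predictor_name: str = "x", curve_points: int = 100) -> RcsFit:
    """Spline-vs-linear logistic nonlinearity test for one predictor.

    A df-degree spline (df + 1 knots) is compared against the linear logit by
    a likelihood-ratio test on df − 1 degrees of freedom.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if x.shape != y.shape:
        raise ContractError("x and y must have equal length")
    if np.unique(x).size < 2:
        raise ContractError("predictor is constant")
    if np.unique(y).size < 2:
        raise ContractError("both outcome classes must be present")
    if len(x) <= 10 * df:
        raise ContractError(f"need n > {10 * df} observations for df={df}")

    knots = rcs_knots(x, df + 1)
    X_spline = sm.add_constant(rcs_basis(x, knots))
    X_linear = sm.add_constant(x)
    fit_s = _fit_logit(X_spline, y)
    fit_l = _fit_logit(X_linear, y)

    # Nesting can be violated by a hair when the spline optimizer stops early.
    ll_s, ll_l = float(fit_s.llf), float(fit_l.llf)
    lrt = max(0.0, 2.0 * (ll_s - ll_l))
    lrt_df = df - 1

    grid = np.linspace(x.min(), x.max(), curve_points)
    Xg = sm.add_constant(rcs_basis(grid, knots), has_constant="add")
    eta = Xg @ fit_s.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, fit_s.cov_params(), Xg))
    curve = pd.DataFrame({
        "value": grid,
        "probability": expit(eta),
        "lower": expit(eta - 1.96 * se),
        "upper": expit(eta + 1.96 * se),
    })
    return RcsFit(
        predictor_name=predictor_name,
        knots=knots,
        coefficients=np.asarray(fit_s.params),
        loglik_spline=ll_s,
        loglik_linear=ll_l,
        lrt_stat=lrt,
        lrt_df=lrt_df,
        lrt_p=float(chi2.sf(lrt, lrt_df)),
        curve=curve,
    )


# --------------------------------------------------------------------------
# Shapley attribution

@dataclass
class ShapSummary:
    feature_names: tuple[str, ...]
    base_value: float
    contributions: np.ndarray  # n_samples × n_features
    mean_abs: np.ndarray
    normalized_importance: np.ndarray

    def importance_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "mean_abs_attribution": self.mean_abs,
            "normalized_importance": self.normalized_importance,
        })

    def long_table(self, subject_ids=None) -> pd.DataFrame:
        n = self.contributions.shape[0]
        ids = list(subject_ids) if subject_ids is not None else list(range(n))
        rows = [
            {"subject": ids[i], "feature": f, "attribution": self.contributions[i, j]}
            for i in range(n)
            for j, f in enumerate(self.feature_names)
        ]
        return pd.DataFrame(rows, columns=["subject", "feature", "attribution"])


def normalize_importance(mean_abs: np.ndarray) -> np.ndarray:
    """Importance weights summing to 1; scale-invariant in the attributions."""
    mean_abs = np.asarray(mean_abs, dtype=np.float64)
    total = mean_abs.sum()
    if total <= 0:
        return np.full(len(mean_abs), 1.0 / len(mean_abs))
    return mean_abs / total


def shap_summary(model: TrainedModel, data: pd.DataFrame,
                 background: pd.DataFrame | None = None,
                 max_background: int = 100, seed: int = 0) -> ShapSummary:
    """Exact Shapley attributions of class-1 probability for every sample.

    The value function of a coalition S is the background-marginal expectation
    of the model output with S's columns taken from the explained sample.
    All 2^d coalitions are enumerated (d ≤ 8), so the attributions are exact
    and additivity is structural, not approximate.
    """
    data = pd.DataFrame(data)
    names = model.feature_names
    missing = [f for f in names if f not in data.columns]
    if missing:
        raise ContractError(f"data is missing model features {missing}")
    X = data[list(names)].to_numpy(dtype=np.float64)
    d = len(names)
    if d > 12:
        raise ContractError("exhaustive Shapley enumeration is limited to 12 features")

    if background is None:
        bg = X
    else:
        background = pd.DataFrame(background)
        bg = background[list(names)].to_numpy(dtype=np.float64)
    if len(bg) > max_background:
        rng = np.random.default_rng(seed)
        bg = bg[rng.choice(len(bg), size=max_background, replace=False)]

    n, B = len(X), len(bg)
    X_rep = np.repeat(X, B, axis=0)          # (n·B, d)
    bg_tile = np.tile(bg, (n, 1))            # (n·B, d)

    def predict(arr: np.ndarray) -> np.ndarray:
        return model.predict_proba(pd.DataFrame(arr, columns=list(names)))

    v = np.empty((1 << d, n))
    for mask in range(1 << d):
        if mask == (1 << d) - 1:
            v[mask] = predict(X)
            continue
        sel = np.array([(mask >> j) & 1 for j in range(d)], dtype=bool)
        Z = np.where(sel, X_rep, bg_tile)
        v[mask] = predict(Z).reshape(n, B).mean(axis=1)

    weights = np.array([factorial(s) * factorial(d - s - 1) / factorial(d)
                        for s in range(d)])
    phi = np.zeros((n, d))
    popcount = np.array([bin(m).count("1") for m in range(1 << d)])
    for j in range(d):
        bit = 1 << j
        for mask in range(1 << d):
            if mask & bit:
                continue
            phi[:, j] += weights[popcount[mask]] * (v[mask | bit] - v[mask])

    mean_abs = np.abs(phi).mean(axis=0)
    normalized = normalize_importance(mean_abs)
    return ShapSummary(
        feature_names=tuple(names),
        base_value=float(v[0].mean()) if B else float("nan"),
        contributions=phi,
        mean_abs=mean_abs,
        normalized_importance=normalized,
    )


def shap_base_values(model: TrainedModel, data: pd.DataFrame,
                     background: pd.DataFrame | None = None,
                     max_background: int = 100, seed: int = 0) -> np.ndarray:
    """Per-sample base value (coalition-∅ value); constant across samples."""
    summary = shap_summary(model, data, background, max_background, seed)
    return np.full(len(summary.contributions), summary.base_value)


# --------------------------------------------------------------------------
# subgroup analysis

def partition_strata(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Row masks for the four demographic strata (sex, and age at 60 years)."""
    sex = table["sex"].astype(str).str.lower()
    age = table["age_years"].to_numpy()
    return {
        "male": (sex == "male").to_numpy(),
        "female": (sex == "female").to_numpy(),
        "older": age >= OLDER_AGE_CUTOFF,
        "younger": age < OLDER_AGE_CUTOFF,
    }


def subgroup_analysis(table: pd.DataFrame, sizes=(1, 2, 3, 4), families=None,
                      n_folds: int = 5, seed: int = 0, min_per_class: int = 5,
                      feature_names=None, **search_kwargs):
    """Re-run the subset search within each demographic stratum.

    Returns (results, warnings): results maps stratum name → ranked
    SubsetResult list; degenerate strata (a missing class or fewer than
    ``min_per_class`` subjects per class) are skipped and reported as
    machine-readable warning records.
    """
    from oxiscreen.model_dev import ALL_FAMILIES
    from oxiscreen.oximetry_summary import FEATURE_NAMES

    families = families if families is not None else ALL_FAMILIES
    feature_names = feature_names if feature_names is not None else FEATURE_NAMES
    for col in ("label", "sex", "age_years"):
        if col not in table.columns:
            raise ContractError(f"subgroup analysis requires a {col!r} column")

    results: dict[str, list[SubsetResult]] = {}
    warnings: list[dict] = []
    for name, mask in partition_strata(table).items():
        sub = table.loc[mask]
        y = sub["label"].to_numpy().astype(int)
        counts = np.bincount(y, minlength=2)
        if counts.min() < max(min_per_class, n_folds):
            warnings.append({"stratum": name, "n": int(mask.sum()),
                             "n_class0": int(counts[0]), "n_class1": int(counts[1]),
                             "reason": "degenerate stratum: too few subjects per class"})
            continue
        results[name] = subset_search(sub[list(feature_names)], y, sizes=sizes,
                                      families=families, n_folds=n_folds, seed=seed,
                                      feature_names=feature_names, **search_kwargs)
    return results, warnings
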