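"""Model development: scaling, SMOTE-in-fold cross-validation, subset search.

The six classifier families are configured from the published hyperparameter
table and delegated to scikit-learn estimators; the protocol around them
(z-scoring fitted on training data only, minority oversampling confined to
training folds, stratified 5-fold CV, exhaustive 1-4-parameter subset search
ranked by F1, retraining without oversampling, external validation) is what
this module owns.
"""

from __future__ import annotations

import itertools
import pickle
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from oxiscreen.errors import ConfigurationError, ContractError
from oxiscreen.oximetry_summary import FEATURE_NAMES


class ModelFamily(str, Enum):
    LOGISTIC = "LOGISTIC"
    SVM_RBF = "SVM_RBF"
    RANDOM_FOREST = "RANDOM_FOREST"
    GBT_SECOND_ORDER = "GBT_SECOND_ORDER"
    GBT_LEAFWISE = "GBT_LEAFWISE"
    GBT_ORDERED = "GBT_ORDERED"


#: Published per-family hyperparameters; only these keys may be overridden.
PUBLISHED_HYPERPARAMETERS: dict[ModelFamily, dict] = {
    ModelFamily.LOGISTIC: {"C": 1.0, "penalty": "l2", "tol": 1e-4},
    ModelFamily.SVM_RBF: {"C": 1.0, "gamma": "scale", "kernel": "rbf"},
    ModelFamily.RANDOM_FOREST: {"criterion": "gini", "max_features": "sqrt",
                                "n_estimators": 100},
    ModelFamily.GBT_SECOND_ORDER: {"learning_rate": 0.3, "reg_lambda": 1,
                                   "n_estimators": 100, "booster": "gbtree"},
    ModelFamily.GBT_LEAFWISE: {"learning_rate": 0.1, "n_estimators": 100,
                               "boosting_type": "gbdt"},
    ModelFamily.GBT_ORDERED: {"learning_rate": 0.03, "n_estimators": 100,
                              "loss_function": "Logloss", "l2_leaf_reg": 3},
}

ALL_FAMILIES = tuple(ModelFamily)


@dataclass
class ModelSpec:
    family: ModelFamily
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.family = ModelFamily(self.family)
        allowed = set(PUBLISHED_HYPERPARAMETERS[self.family])
        unknown = set(self.hyperparameters) - allowed
        if unknown:
            raise ConfigurationError(
                f"{self.family.value}: hyperparameters {sorted(unknown)} are not in "
                f"the published table (allowed: {sorted(allowed)})")

    def resolved(self) -> dict:
        return {**PUBLISHED_HYPERPARAMETERS[self.family], **self.hyperparameters}


class MarginProbabilitySVC:
    """RBF-SVM scoring class-1 probability as a logistic link on the margin.

    Deterministic replacement for Platt rescaling: the 0.5 probability
    threshold coincides with the standard sign rule, and any rank-based
    metric is unaffected.
    """

    def __init__(self, C: float = 1.0, gamma="scale", kernel: str = "rbf",
                 random_state: int | None = None):
        self._svc = SVC(C=C, gamma=gamma, kernel=kernel, random_state=random_state)

    def fit(self, X, y):
        self._svc.fit(X, y)
        return self

    def predict_proba(self, X):
        p1 = expit(self._svc.decision_function(X))
        return np.column_stack([1.0 - p1, p1])


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator backing a family.

    Hyperparameter keys with no scikit-learn counterpart (booster flavour
    strings, ordered-boosting options) are accepted for manifest fidelity and
    reported by :func:`resolved_hyperparameters` as unmapped.
    """
    hp = spec.resolved()
    fam = spec.family
    if fam is ModelFamily.LOGISTIC:
        if hp["penalty"] != "l2":
            raise ConfigurationError("only the published l2 penalty is supported")
        # l2 is sklearn's default; passing `penalty` explicitly is deprecated
        return LogisticRegression(C=hp["C"], tol=hp["tol"],
                                  max_iter=1000, random_state=spec.seed)
    if fam is ModelFamily.SVM_RBF:
        return MarginProbabilitySVC(C=hp["C"], gamma=hp["gamma"], kernel=hp["kernel"],
                                    random_state=spec.seed)
    if fam is ModelFamily.RANDOM_FOREST:
        return RandomForestClassifier(criterion=hp["criterion"],
                                      max_features=hp["max_features"],
                                      n_estimators=hp["n_estimators"],
                                      random_state=spec.seed)
    if fam is ModelFamily.GBT_SECOND_ORDER:
        return HistGradientBoostingClassifier(learning_rate=hp["learning_rate"],
                                              max_iter=hp["n_estimators"],
                                              l2_regularization=hp["reg_lambda"],
                                              random_state=spec.seed)
    if fam is ModelFamily.GBT_LEAFWISE:
        return HistGradientBoostingClassifier(learning_rate=hp["learning_rate"],
                                              max_iter=hp["n_estimators"],
                                              random_state=spec.seed)
    if fam is ModelFamily.GBT_ORDERED:
        return HistGradientBoostingClassifier(learning_rate=hp["learning_rate"],
                                              max_iter=hp["n_estimators"],
                                              l2_regularization=hp["l2_leaf_reg"],
                                              random_state=spec.seed)
    raise ConfigurationError(f"unknown family {fam}")


_UNMAPPED_KEYS = {"booster", "boosting_type", "loss_function"}


def resolved_hyperparameters(spec: ModelSpec) -> dict:
    """Manifest record: table values split into mapped and unmapped keys."""
    hp = spec.resolved()
    return {
        "family": spec.family.value,
        "mapped": {k: v for k, v in hp.items() if k not in _UNMAPPED_KEYS},
        "unmapped": {k: v for k, v in hp.items() if k in _UNMAPPED_KEYS},
    }


# --------------------------------------------------------------------------
# scaling and oversampling

@dataclass
class ZScaler:
    """Per-feature (μ, σ) standardization; σ = 0 features transform to 0."""

    mu: np.ndarray
    sigma: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "ZScaler":
        X = np.asarray(X, dtype=np.float64)
        if X.size == 0:
            raise ContractError("cannot fit a scaler on an empty table")
        return cls(mu=X.mean(axis=0), sigma=X.std(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        sigma = np.where(self.sigma == 0, 1.0, self.sigma)
        out = (X - self.mu) / sigma
        out[:, self.sigma == 0] = 0.0
        return out


def zscore_fit_apply(train: np.ndarray, *others: np.ndarray):
    """Fit (μ, σ) on the training table only and transform all tables."""
    scaler = ZScaler.fit(train)
    return (scaler.transform(train), *[scaler.transform(o) for o in others], scaler)


def smote_oversample(X: np.ndarray, y: np.ndarray, k: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by interpolated synthetic minority samples.

    Each synthetic sample is ``x_i + λ (x̂_i − x_i)`` with λ ~ Uniform(0, 1)
    and x̂_i one of x_i's k nearest minority neighbors. Originals are
    preserved verbatim; output classes are balanced.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ContractError("smote_oversample requires both classes present")
    if len(classes) > 2:
        raise ContractError("smote_oversample supports binary labels only")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()

    minority = classes[np.argmin(counts)]
    X_min = X[y == minority]
    n_needed = int(abs(counts[0] - counts[1]))
    rng = np.random.default_rng(seed)

    if len(X_min) == 1:
        synth = np.repeat(X_min, n_needed, axis=0)
    else:
        k_eff = min(k, len(X_min) - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
        _, neighbor_idx = nn.kneighbors(X_min)  # column 0 is the point itself
        base = rng.integers(0, len(X_min), size=n_needed)
        pick = rng.integers(1, k_eff + 1, size=n_needed)
        lam = rng.uniform(0.0, 1.0, size=n_needed)
        xi = X_min[base]
        xhat = X_min[neighbor_idx[base, pick]]
        synth = xi + lam[:, None] * (xhat - xi)

    X_aug = np.vstack([X, synth])
    y_aug = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_aug, y_aug


# --------------------------------------------------------------------------
# evaluation

@dataclass
class EvalMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    ppv: float
    npv: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("tp", "fp", "tn", "fn", "accuracy", "sensitivity", "specificity",
                 "f1", "auc", "ppv", "npv")}


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the concordance probability via average ranks; ties count ½."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ContractError("AUC undefined: only one class present")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def evaluate(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> EvalMetrics:
    """Confusion counts at the threshold plus the seven summary metrics.

    AUC is NaN when only one class is present; the threshold metrics are
    still returned.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ContractError("scores and labels must have equal length")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = _ratio(tp, tp + fn)
    ppv = _ratio(tp, tp + fp)
    try:
        auc = rank_auc(scores, labels)
    except ContractError:
        auc = float("nan")
    return EvalMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        sensitivity=sens,
        specificity=_ratio(tn, tn + fp),
        f1=_ratio(2 * ppv * sens, ppv + sens) if np.isfinite(ppv + sens) else float("nan"),
        auc=auc,
        ppv=ppv,
        npv=_ratio(tn, tn + fn),
    )


def mean_metrics(fold_metrics: list[EvalMetrics]) -> EvalMetrics:
    """Field-wise aggregation: counts summed, proportions averaged over folds."""
    return EvalMetrics(
        tp=sum(m.tp for m in fold_metrics),
        fp=sum(m.fp for m in fold_metrics),
        tn=sum(m.tn for m in fold_metrics),
        fn=sum(m.fn for m in fold_metrics),
        accuracy=float(np.mean([m.accuracy for m in fold_metrics])),
        sensitivity=float(np.mean([m.sensitivity for m in fold_metrics])),
        specificity=float(np.mean([m.specificity for m in fold_metrics])),
        f1=float(np.mean([m.f1 for m in fold_metrics])),
        auc=float(np.mean([m.auc for m in fold_metrics])),
        ppv=float(np.mean([m.ppv for m in fold_metrics])),
        npv=float(np.mean([m.npv for m in fold_metrics])),
    )


# --------------------------------------------------------------------------
# cross-validation

@dataclass
class SubsetResult:
    features: tuple[str, ...]
    spec: ModelSpec
    fold_metrics: list[EvalMetrics]
    metrics: EvalMetrics  # means over folds


def fit_fold(X: np.ndarray, y: np.ndarray, train_idx: np.ndarray, spec: ModelSpec,
             fold_seed: int, smote_k: int = 5, scale_in_fold: bool = True,
             global_scaler: ZScaler | None = None):
    """Train one fold's artifacts from training rows only.

    Returns (scaler, estimator). Validation labels are never consulted, which
    is what the no-leakage property tests verify.
    """
    X_tr, y_tr = X[train_idx], y[train_idx]
    scaler = ZScaler.fit(X_tr) if scale_in_fold else global_scaler
    if scaler is None:
        raise ContractError("scale_in_fold=False requires a pre-fitted global scaler")
    X_tr_s = scaler.transform(X_tr)
    X_aug, y_aug = smote_oversample(X_tr_s, y_tr, k=smote_k, seed=fold_seed)
    est = build_estimator(ModelSpec(spec.family, dict(spec.hyperparameters), seed=fold_seed))
    est.fit(X_aug, y_aug)
    return scaler, est


def cross_validate(X: pd.DataFrame, y: np.ndarray, spec: ModelSpec, n_folds: int = 5,
                   seed: int = 0, smote_k: int = 5, threshold: float = 0.5,
                   scale_in_fold: bool = True) -> SubsetResult:
    """Stratified k-fold CV with scaling and SMOTE confined to training folds."""
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < n_folds:
        raise ContractError(f"need at least {n_folds} subjects per class for {n_folds}-fold CV")

    X_arr = X.to_numpy(dtype=np.float64)
    global_scaler = None if scale_in_fold else ZScaler.fit(X_arr)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_metrics: list[EvalMetrics] = []
    for fold_no, (train_idx, val_idx) in enumerate(skf.split(X_arr, y)):
        scaler, est = fit_fold(X_arr, y, train_idx, spec, fold_seed=seed + fold_no,
                               smote_k=smote_k, scale_in_fold=scale_in_fold,
                               global_scaler=global_scaler)
        scores = est.predict_proba(scaler.transform(X_arr[val_idx]))[:, 1]
        fold_metrics.append(evaluate(scores, y[val_idx], threshold=threshold))
    return SubsetResult(features=tuple(X.columns), spec=spec,
                        fold_metrics=fold_metrics, metrics=mean_metrics(fold_metrics))


# --------------------------------------------------------------------------
# subset search and finalization

def enumerate_subsets(sizes, feature_names=FEATURE_NAMES) -> list[tuple[str, ...]]:
    """All unordered feature subsets of the requested sizes, in deterministic order."""
    subsets: list[tuple[str, ...]] = []
    for size in sorted(set(sizes)):
        if not 1 <= size <= len(feature_names):
            raise ConfigurationError(f"subset size {size} out of range")
        subsets.extend(itertools.combinations(feature_names, size))
    return subsets


def subset_search(X: pd.DataFrame, y: np.ndarray, sizes=(1, 2, 3, 4),
                  families=ALL_FAMILIES, n_folds: int = 5, seed: int = 0,
                  smote_k: int = 5, threshold: float = 0.5,
                  scale_in_fold: bool = True,
                  feature_names=FEATURE_NAMES) -> list[SubsetResult]:
    """Cross-validate every feature subset × family and rank the cells.

    Ranking: mean F1 descending, ties broken by mean AUC descending, then by
    lexicographic feature names. Fold assignment depends only on (y, seed), so
    every cell sees identical splits.
    """
    X = pd.DataFrame(X)
    missing = [f for f in feature_names if f not in X.columns]
    if missing:
        raise ConfigurationError(f"feature table is missing columns {missing}")
    families = [ModelFamily(f) for f in families]

    results: list[SubsetResult] = []
    for subset in enumerate_subsets(sizes, feature_names):
        X_sub = X[list(subset)]
        for family in families:
            spec = ModelSpec(family=family, seed=seed)
            results.append(cross_validate(X_sub, y, spec, n_folds=n_folds, seed=seed,
                                          smote_k=smote_k, threshold=threshold,
                                          scale_in_fold=scale_in_fold))
    return rank_results(results)


def rank_results(results: list[SubsetResult]) -> list[SubsetResult]:
    """Order cells by mean F1 desc, then mean AUC desc, then feature names."""
    return sorted(results, key=lambda r: (-r.metrics.f1, -r.metrics.auc, r.features))


def results_table(results: list[SubsetResult]) -> pd.DataFrame:
    """Ranked long-format table (one row per subset × family cell)."""
    rows = []
    for rank, r in enumerate(results, start=1):
        row = {"rank": rank, "features": "+".join(r.features),
               "n_features": len(r.features), "family": r.spec.family.value}
        row.update({f"mean_{k}": v for k, v in r.metrics.as_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TrainedModel:
    spec: ModelSpec
    feature_names: tuple[str, ...]
    scaler: ZScaler
    estimator: object

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Class-1 probabilities; columns aligned by name, order-insensitive."""
        X = pd.DataFrame(X)
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise ContractError(f"prediction input is missing features {missing}")
        arr = X[list(self.feature_names)].to_numpy(dtype=np.float64)
        return self.estimator.predict_proba(self.scaler.transform(arr))[:, 1]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TrainedModel):
            raise ContractError(f"{path} does not contain a TrainedModel")
        return model


def finalize_and_validate(best: SubsetResult, internal_X: pd.DataFrame,
                          internal_y: np.ndarray, external_X: pd.DataFrame,
                          external_y: np.ndarray, threshold: float = 0.5
                          ) -> tuple[TrainedModel, EvalMetrics, EvalMetrics]:
    """Retrain the selected cell on the full internal cohort without
    oversampling, then score the external cohort with the internal scaler."""
    internal_X = pd.DataFrame(internal_X)
    external_X = pd.DataFrame(external_X)
    missing = [f for f in best.features if f not in external_X.columns]
    if missing:
        raise ContractError(f"external cohort is missing features {missing}")

    arr = internal_X[list(best.features)].to_numpy(dtype=np.float64)
    scaler = ZScaler.fit(arr)
    est = build_estimator(best.spec)
    est.fit(scaler.transform(arr), np.asarray(internal_y).astype(int))
    model = TrainedModel(spec=best.spec, feature_names=tuple(best.features),
                         scaler=scaler, estimator=est)
    internal_metrics = evaluate(model.predict_proba(internal_X),
                                np.asarray(internal_y).astype(int), threshold)
    external_metrics = evaluate(model.predict_proba(external_X),
                                np.asarray(external_y).astype(int), threshold)
    return model, internal_metrics, external_metrics
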