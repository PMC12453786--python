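"""Benchmark harness: train and score the 12-classifier panel.

Twelve classifier configurations spanning ensemble (XGBoost, RF, GBoost,
LGBM, AdaBoost, ET), probabilistic (NB), distance (KNN), linear (SVM,
SGD), tree (DT) and neural (ANN) families are trained on an encoded
cohort and scored with the seven-metric suite.  Model fitting delegates
to the established scikit-learn / xgboost / lightgbm implementations —
this is the one off-the-shelf stage of the pipeline; metrics, ADASYN and
FDOSM are authored here from their defining equations.

The headline product is a decision matrix (models x 7 criteria, in the
canonical order precision, recall, F-score, kappa, Hamming loss, MCC,
accuracy) ready for FDOSM ranking, plus 5-fold cross-validation
train/validation means feeding the overfitting report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from . import metrics as _metrics
from .fdosm import DecisionMatrix
from .metrics import MetricReport, OverfitReport, confusion, overfit, report

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "default_specs",
    "FittedModel",
    "train",
    "evaluate",
    "cross_validate",
    "BenchResult",
    "run_bench",
]

#: Display names of the benchmark metrics in decision-matrix column order.
CRITERIA = ("Precision", "Recall", "F-score", "Kappa", "Hamming loss", "MCC", "Accuracy")
_METRIC_TO_CRITERION = dict(zip(_metrics.METRIC_NAMES, CRITERIA))

MODEL_NAMES = ("XGBoost", "KNN", "DT", "RF", "SVM", "ANN", "SGD",
               "GBoost", "LGBM", "AdaBoost", "NB", "ET")


def _build(name: str, seed: int, regularized: bool, overrides: Mapping | None):
    """Instantiate one configured learner from the panel."""
    params = dict(overrides or {})
    if name == "XGBoost":
        base = dict(n_estimators=100, max_depth=6, learning_rate=0.3,
                    gamma=0, reg_alpha=0, reg_lambda=1, random_state=seed,
                    n_jobs=1, verbosity=0)
        if regularized:
            base.update(reg_lambda=0.2, max_depth=4, colsample_bytree=0.5)
        return XGBClassifier(**{**base, **params})
    if name == "KNN":
        return KNeighborsClassifier(**{**dict(n_neighbors=5, weights="uniform",
                                              metric="minkowski"), **params})
    if name == "DT":
        return DecisionTreeClassifier(**{**dict(criterion="gini", splitter="best",
                                                min_samples_split=2, random_state=seed), **params})
    if name == "RF":
        return RandomForestClassifier(**{**dict(n_estimators=100, criterion="gini",
                                                min_samples_split=2, random_state=seed,
                                                n_jobs=1), **params})
    if name == "SVM":
        return SVC(**{**dict(C=1.0, kernel="rbf", tol=0.001, random_state=seed), **params})
    if name == "ANN":
        base = dict(hidden_layer_sizes=(100,), activation="relu", solver="adam",
                    learning_rate_init=0.2, alpha=0.0001, max_iter=200, random_state=seed)
        if regularized:
            base.update(early_stopping=True, n_iter_no_change=100)
        return MLPClassifier(**{**base, **params})
    if name == "SGD":
        return SGDClassifier(**{**dict(penalty="l2", alpha=0.0001, learning_rate="adaptive",
                                       eta0=0.2, max_iter=1000, tol=0.001,
                                       random_state=seed), **params})
    if name == "GBoost":
        return GradientBoostingClassifier(**{**dict(n_estimators=100, learning_rate=0.1,
                                                    max_depth=3, min_samples_split=2,
                                                    random_state=seed), **params})
    if name == "LGBM":
        return LGBMClassifier(**{**dict(n_estimators=100, learning_rate=0.1, num_leaves=31,
                                        min_child_samples=20, random_state=seed,
                                        n_jobs=1, verbose=-1), **params})
    if name == "AdaBoost":
        return AdaBoostClassifier(**{**dict(n_estimators=50, learning_rate=1.0,
                                            random_state=seed), **params})
    if name == "NB":
        return GaussianNB(**{**dict(var_smoothing=1e-9), **params})
    if name == "ET":
        return ExtraTreesClassifier(**{**dict(n_estimators=100, criterion="gini",
                                              min_samples_split=2, min_samples_leaf=1,
                                              random_state=seed, n_jobs=1), **params})
    raise ValueError(f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}")


@dataclass(frozen=True)
class ModelSpec:
    """One named classifier configuration.

    ``params`` overrides individual hyperparameters; ``regularized``
    switches to the alternative anti-overfitting settings (stronger
    shrinkage, shallower trees, feature subsampling, early stopping).
    """

    name: str
    seed: int = 0
    params: Mapping | None = None
    regularized: bool = False

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; valid names: {', '.join(MODEL_NAMES)}")

    def build(self):
        return _build(self.name, self.seed, self.regularized, self.params)


def default_specs(seed: int = 0, regularized: bool = False,
                  names: Sequence[str] = MODEL_NAMES) -> list[ModelSpec]:
    """The full 12-model panel at its default settings."""
    return [ModelSpec(n, seed=seed, regularized=regularized) for n in names]


@dataclass
class FittedModel:
    """Fitted learner plus the label encoding and training schema."""

    spec: ModelSpec
    estimator: object
    label_encoder: LabelEncoder
    feature_names: tuple[str, ...]

    @property
    def classes(self) -> tuple:
        return tuple(self.label_encoder.classes_)

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        if tuple(X.columns) != self.feature_names:
            raise ValueError(
                f"schema mismatch: model was trained on {list(self.feature_names)}, "
                f"got {list(X.columns)}"
            )
        return X.to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.label_encoder.inverse_transform(self.estimator.predict(self._check(X)))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        arr = self._check(X)
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(arr)
        # Margin-based learners without probabilities: one-hot the prediction.
        pred = self.estimator.predict(arr)
        proba = np.zeros((len(arr), len(self.classes)))
        proba[np.arange(len(arr)), pred] = 1.0
        return proba


def train(spec: ModelSpec, X: pd.DataFrame, y: Sequence) -> FittedModel:
    """Fit one spec on an encoded, fully imputed training table."""
    X = pd.DataFrame(X)
    le = LabelEncoder().fit(np.asarray(y))
    est = spec.build()
    est.fit(X.to_numpy(dtype=float), le.transform(np.asarray(y)))
    return FittedModel(spec, est, le, tuple(X.columns))


def evaluate(handle: FittedModel, X: pd.DataFrame, y: Sequence,
             classes: Sequence | None = None) -> MetricReport:
    """Score a fitted model on a test table with the seven-metric suite."""
    pred = handle.predict(X)
    return report(confusion(np.asarray(y), pred, classes=classes or handle.classes))


def cross_validate(spec: ModelSpec, X: pd.DataFrame, y: Sequence, k: int = 5,
                   seed: int = 0) -> tuple[float, float]:
    """K-fold stratified CV accuracy means for train folds and validation folds."""
    if k < 2:
        raise ValueError(f"K must be >= 2, got {k}")
    X = pd.DataFrame(X)
    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} rows; needs >= K={k} for stratified CV"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    train_scores, val_scores = [], []
    for tr, va in skf.split(X, y):
        handle = train(spec, X.iloc[tr], y[tr])
        train_scores.append(float(np.mean(handle.predict(X.iloc[tr]) == y[tr])))
        val_scores.append(float(np.mean(handle.predict(X.iloc[va]) == y[va])))
    return float(np.mean(train_scores)), float(np.mean(val_scores))


@dataclass
class BenchResult:
    """Everything a bench run produces, keyed by model name."""

    reports: dict[str, MetricReport]
    overfit_reports: dict[str, OverfitReport]
    handles: dict[str, FittedModel]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def decision_matrix(self) -> DecisionMatrix:
        """Models x 7 criteria; all benefit except Hamming loss (cost)."""
        rows = {
            name: {_METRIC_TO_CRITERION[m]: getattr(rep, m) for m in _metrics.METRIC_NAMES}
            for name, rep in self.reports.items()
        }
        df = pd.DataFrame(rows).T[list(CRITERIA)]
        directions = {c: ("cost" if c == "Hamming loss" else "benefit") for c in CRITERIA}
        return DecisionMatrix(df, directions)

    def metric_table(self, ndigits: int = 3) -> pd.DataFrame:
        return pd.DataFrame({n: r.rounded(ndigits) for n, r in self.reports.items()}).T

    def overfit_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                n: {"train_mean": o.train_mean, "validation_mean": o.validation_mean,
                    "overfit_pct": o.overfit_pct, "status": o.status}
                for n, o in self.overfit_reports.items()
            }
        ).T


def run_bench(specs: Sequence[ModelSpec], X_train: pd.DataFrame, y_train: Sequence,
              X_test: pd.DataFrame, y_test: Sequence, cv: int | None = 5,
              seed: int = 0) -> BenchResult:
    """Train, test and (optionally) cross-validate every spec.

    Per-model failures are recorded and the run continues.  Set
    ``cv=None`` to skip cross-validation.
    """
    if not specs:
        raise ValueError("need at least one model spec")
    reports, overfits, handles, failures = {}, {}, {}, {}
    for spec in specs:
        try:
            handle = train(spec, X_train, y_train)
            reports[spec.name] = evaluate(handle, X_test, y_test)
            handles[spec.name] = handle
            if cv is not None:
                tr_mean, va_mean = cross_validate(spec, X_train, y_train, k=cv, seed=seed)
                overfits[spec.name] = overfit(tr_mean, va_mean)
        except Exception as exc:  # noqa: BLE001 — a failed model must not kill the run
            failures[spec.name] = f"{type(exc).__name__}: {exc}"
    return BenchResult(reports, overfits, handles, failures)
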