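"""Local and global model explanations for the diagnostic classifiers.

Local explanations follow the LIME recipe: perturb the instance, query
the model's class probability on the perturbations, and fit a locally
weighted linear surrogate whose coefficients are the per-feature weights.
Numeric features are perturbed with Gaussian noise scaled by the
background standard deviation; binary features are flipped with
probability 0.3.  Sample weights use an exponential kernel on the
standardized Euclidean distance from the instance.

Global importance is either the mean absolute local weight over a
stratified sample of instances, or sklearn's permutation importance —
the two standard readings of "global feature importance from a local
explainer"; both are offered because the aggregation is a modelling
choice, not part of the local method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Ridge

from .bench import FittedModel
from .synth import LABEL_COL

__all__ = [
    "LocalExplanation",
    "GlobalImportance",
    "predict_proba",
    "explain_local",
    "explain_global",
]


def predict_proba(handle: FittedModel, instance: pd.Series | pd.DataFrame) -> pd.Series:
    """Normalized class-probability vector for a single instance."""
    row = instance.to_frame().T if isinstance(instance, pd.Series) else pd.DataFrame(instance)
    if len(row) != 1:
        raise ValueError(f"expected a single instance, got {len(row)} rows")
    proba = handle.predict_proba(row)[0]
    proba = np.clip(proba, 0.0, None)
    proba = proba / proba.sum() if proba.sum() > 0 else np.full_like(proba, 1.0 / len(proba))
    return pd.Series(proba, index=list(handle.classes))


@dataclass
class LocalExplanation:
    """Per-feature surrogate weights for one instance and one target class."""

    instance_id: object
    target_class: object
    class_probs: pd.Series
    weights: pd.Series
    values: pd.Series
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        """Two-column (Weight, Value) layout, one row per feature."""
        return pd.DataFrame({"Weight": self.weights, "Value": self.values})


def _perturb(x: np.ndarray, bg_std: np.ndarray, is_binary: np.ndarray,
             n_samples: int, rng: np.random.Generator) -> np.ndarray:
    Z = np.tile(x, (n_samples, 1)).astype(float)
    num = ~is_binary
    Z[:, num] += rng.standard_normal((n_samples, int(num.sum()))) * bg_std[num]
    flips = rng.random((n_samples, int(is_binary.sum()))) < 0.3
    Z[:, is_binary] = np.where(flips, 1.0 - Z[:, is_binary], Z[:, is_binary])
    Z[0] = x  # keep the instance itself in the local sample
    return Z


def explain_local(handle: FittedModel, instance: pd.Series, background: pd.DataFrame,
                  n_samples: int = 1000, seed: int = 0, target_class: object = None,
                  num_features: int | None = None, kernel_width: float | None = None
                  ) -> LocalExplanation:
    """Perturbation-based sparse linear surrogate around one instance.

    Weights come from a kernel-weighted ridge regression of the target
    class probability on the standardized perturbed features; positive
    weight means the feature pushes the prediction toward
    ``target_class`` (default: the predicted class).  Deterministic given
    ``seed``.  ``num_features`` keeps only the largest-|weight| features
    in the report (default: all).
    """
    if n_samples < 10:
        raise ValueError(f"n_samples must be >= 10, got {n_samples}")
    background = pd.DataFrame(background)
    features = list(handle.feature_names)
    if list(background.columns) != features:
        raise ValueError("background schema does not match the model")
    x = instance[features].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    bg = background.to_numpy(dtype=float)
    is_binary = np.array([set(np.unique(bg[:, j])) <= {0.0, 1.0} for j in range(bg.shape[1])])
    bg_std = bg.std(axis=0)
    bg_std[bg_std == 0] = 1.0

    Z = _perturb(x, bg_std, is_binary, n_samples, rng)
    probs = predict_proba(handle, instance)
    if target_class is None:
        target_class = probs.idxmax()
    target_idx = list(handle.classes).index(target_class)
    yz = handle.predict_proba(pd.DataFrame(Z, columns=features))[:, target_idx]

    Zs = (Z - x) / bg_std  # standardized displacement from the instance
    dist = np.sqrt((Zs**2).sum(axis=1))
    width = kernel_width if kernel_width is not None else 0.75 * np.sqrt(len(features))
    sample_weight = np.exp(-(dist**2) / width**2)

    surrogate = Ridge(alpha=1.0)
    surrogate.fit(Zs, yz, sample_weight=sample_weight)
    weights = pd.Series(surrogate.coef_, index=features)
    if num_features is not None:
        keep = weights.abs().nlargest(num_features).index
        weights = weights.loc[[f for f in features if f in keep]]

    return LocalExplanation(
        instance_id=instance.name,
        target_class=target_class,
        class_probs=probs,
        weights=weights,
        values=instance[weights.index],
        n_samples=n_samples,
    )


@dataclass
class GlobalImportance:
    """Nonnegative per-feature importance scores, reported descending."""

    scores: pd.Series
    method: str

    def to_frame(self) -> pd.DataFrame:
        return self.scores.sort_values(ascending=False).to_frame("importance")


def explain_global(handle: FittedModel, table: pd.DataFrame, method: str = "mean_local",
                   label_col: str = LABEL_COL, n_instances: int = 100, n_samples: int = 500,
                   seed: int = 0) -> GlobalImportance:
    """Global feature importance for a fitted model over an evaluation table.

    ``mean_local``: mean absolute local surrogate weight over a
    label-stratified sample of up to ``n_instances`` rows.
    ``permutation``: accuracy drop under per-column permutation
    (negative drops clipped to 0).
    """
    if table.empty:
        raise ValueError("empty evaluation table")
    if method not in ("mean_local", "permutation"):
        raise ValueError(f"method must be 'mean_local' or 'permutation', got {method!r}")
    features = list(handle.feature_names)
    X = table[features]
    y = table[label_col] if label_col in table.columns else None

    if method == "permutation":
        if y is None:
            raise ValueError("permutation importance needs the label column")
        est = handle.estimator
        result = permutation_importance(
            est, X.to_numpy(dtype=float), handle.label_encoder.transform(y),
            n_repeats=5, random_state=seed, n_jobs=1,
        )
        scores = pd.Series(np.clip(result.importances_mean, 0.0, None), index=features)
        return GlobalImportance(scores.sort_values(ascending=False), method)

    rng = np.random.default_rng(seed)
    if y is not None and len(table) > n_instances:
        # Stratified subsample: proportional per observed label, >= 1 each.
        picks = []
        for _, group in table.groupby(y, sort=False):
            k = max(1, int(round(n_instances * len(group) / len(table))))
            picks.extend(rng.choice(group.index, size=min(k, len(group)), replace=False))
        sample = table.loc[picks, features]
    else:
        idx = rng.choice(table.index, size=min(n_instances, len(table)), replace=False)
        sample = table.loc[idx, features]

    acc = np.zeros(len(features))
    for i, (_, row) in enumerate(sample.iterrows()):
        exp = explain_local(handle, row, X, n_samples=n_samples, seed=seed + i)
        acc += exp.weights.abs().reindex(features).to_numpy()
    scores = pd.Series(acc / len(sample), index=features)
    return GlobalImportance(scores.sort_values(ascending=False), method)
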