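"""Preprocessing: mean/mode imputation, clinical encoding, ADASYN, splitting.

The pipeline applied to a raw cohort before benchmarking:

1. missing values filled with the column mean (numeric) or mode
   (categorical/binary);
2. categoricals encoded numerically — binary clinical conventions are
   Negative=0 / Positive=1 and Female=0 / Male=1, any category with more
   than two levels becomes a one-hot block;
3. the minority diagnosis oversampled with ADASYN (adaptive synthetic
   sampling), implemented here directly from its defining equations;
4. a per-class (stratified) 70/30 train/test split.

The imputer and encoder are scikit-learn compatible transformers and
compose with sklearn pipelines; :class:`Adasyn` follows the
``fit_resample`` sampler idiom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

from .synth import LABEL_COL

__all__ = [
    "ImputationReport",
    "MeanModeImputer",
    "impute",
    "ClinicalEncoder",
    "encode",
    "AdasynConfig",
    "Adasyn",
    "adasyn",
    "SplitSpec",
    "stratified_split",
]

# Binary-level conventions used by the clinical tables.
_BINARY_CODES: dict[str, float] = {
    "Negative": 0.0, "Positive": 1.0,
    "negative": 0.0, "positive": 1.0,
    "N": 0.0, "P": 1.0,
    "F": 0.0, "M": 1.0,
    "Female": 0.0, "Male": 1.0,
    "female": 0.0, "male": 1.0,
}


def _round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


# ---------------------------------------------------------------------------
# Imputation


@dataclass
class ImputationReport:
    """Fill value and number of cells filled, per feature."""

    fill_values: dict[str, float | str]
    n_filled: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fill_value": self.fill_values, "n_filled": self.n_filled})


class MeanModeImputer(BaseEstimator, TransformerMixin):
    """Fill missing cells with the column mean (numeric) or mode (categorical).

    Columns are treated as categorical when their dtype is non-numeric or
    when their observed values form a subset of {0, 1} (the encoding of
    the binary serology markers); this can be overridden with
    ``categorical_cols``.  The label column is never touched.  Mode ties
    break toward the smallest value.  A column with no observed value at
    all has no defined mean/mode and raises.
    """

    def __init__(self, categorical_cols: Sequence[str] | None = None,
                 label_col: str = LABEL_COL):
        self.categorical_cols = categorical_cols
        self.label_col = label_col

    def _is_categorical(self, s: pd.Series) -> bool:
        if self.categorical_cols is not None:
            return s.name in self.categorical_cols
        if not pd.api.types.is_numeric_dtype(s):
            return True
        observed = s.dropna().unique()
        return len(observed) > 0 and set(np.unique(observed)) <= {0.0, 1.0}

    def fit(self, X: pd.DataFrame, y=None) -> "MeanModeImputer":
        X = pd.DataFrame(X)
        self.fill_values_ = {}
        for col in X.columns:
            if col == self.label_col:
                continue
            observed = X[col].dropna()
            if observed.empty:
                raise ValueError(f"column {col!r} is entirely missing; no mean/mode defined")
            if self._is_categorical(X[col]):
                self.fill_values_[col] = observed.mode().sort_values().iloc[0]
            else:
                self.fill_values_[col] = float(observed.mean())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "fill_values_")
        X = pd.DataFrame(X).copy()
        self.last_report_ = ImputationReport(
            dict(self.fill_values_),
            {c: int(X[c].isna().sum()) for c in self.fill_values_ if c in X.columns},
        )
        for col, value in self.fill_values_.items():
            if col in X.columns:
                X[col] = X[col].fillna(value)
        return X


def impute(table: pd.DataFrame, categorical_cols: Sequence[str] | None = None,
           label_col: str = LABEL_COL) -> tuple[pd.DataFrame, ImputationReport]:
    """Fit-and-apply mean/mode imputation on one table; returns the report."""
    imp = MeanModeImputer(categorical_cols=categorical_cols, label_col=label_col)
    filled = imp.fit(table).transform(table)
    return filled, imp.last_report_


# ---------------------------------------------------------------------------
# Encoding


class ClinicalEncoder(BaseEstimator, TransformerMixin):
    """Encode categorical columns to numbers; numeric columns pass through.

    Two-level columns become a single 0/1 column using the clinical
    conventions (Negative=0/Positive=1, Female=0/Male=1); unknown level
    pairs fall back to sorted order.  Columns with more than two levels
    expand to a one-hot block ``col=level`` with exactly one 1 per row.
    Unseen categories at transform time raise, naming the column.
    """

    def __init__(self, label_col: str = LABEL_COL):
        self.label_col = label_col

    def fit(self, X: pd.DataFrame, y=None) -> "ClinicalEncoder":
        X = pd.DataFrame(X)
        self.binary_maps_: dict[str, dict[object, float]] = {}
        self.onehot_levels_: dict[str, list] = {}
        self.columns_: list[str] = []
        for col in X.columns:
            if col == self.label_col:
                continue
            s = X[col]
            if pd.api.types.is_numeric_dtype(s):
                self.columns_.append(col)
                continue
            levels = sorted(s.dropna().unique())
            if len(levels) <= 2:
                if all(lv in _BINARY_CODES for lv in levels):
                    mapping = {lv: _BINARY_CODES[lv] for lv in levels}
                else:
                    mapping = {lv: float(i) for i, lv in enumerate(levels)}
                self.binary_maps_[col] = mapping
                self.columns_.append(col)
            else:
                self.onehot_levels_[col] = levels
                self.columns_.extend(f"{col}={lv}" for lv in levels)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        X = pd.DataFrame(X)
        out = {}
        for col in X.columns:
            if col == self.label_col:
                continue
            s = X[col]
            if col in self.binary_maps_:
                unseen = set(s.dropna().unique()) - set(self.binary_maps_[col])
                if unseen:
                    raise ValueError(f"unseen categor{'ies' if len(unseen) > 1 else 'y'} "
                                     f"{sorted(map(str, unseen))} in column {col!r}")
                out[col] = s.map(self.binary_maps_[col]).astype(float)
            elif col in self.onehot_levels_:
                levels = self.onehot_levels_[col]
                unseen = set(s.dropna().unique()) - set(levels)
                if unseen:
                    raise ValueError(f"unseen categor{'ies' if len(unseen) > 1 else 'y'} "
                                     f"{sorted(map(str, unseen))} in column {col!r}")
                for lv in levels:
                    out[f"{col}={lv}"] = (s == lv).astype(float)
            else:
                out[col] = s.astype(float)
        return pd.DataFrame(out, index=X.index)[self.columns_]

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Decode binary and one-hot blocks back to their original levels."""
        check_is_fitted(self, "columns_")
        X = pd.DataFrame(X)
        out = {}
        consumed = set()
        for col, mapping in self.binary_maps_.items():
            inv = {v: k for k, v in mapping.items()}
            out[col] = X[col].map(inv)
            consumed.add(col)
        for col, levels in self.onehot_levels_.items():
            block = X[[f"{col}={lv}" for lv in levels]]
            out[col] = block.idxmax(axis=1).str.split("=", n=1).str[1]
            consumed.update(block.columns)
        for col in X.columns:
            if col not in consumed:
                out[col] = X[col]
        return pd.DataFrame(out, index=X.index)


def encode(table: pd.DataFrame, label_col: str = LABEL_COL) -> tuple[pd.DataFrame, pd.Series]:
    """Encode a (fully imputed) table into a feature matrix and label vector."""
    if table.drop(columns=[label_col], errors="ignore").isna().any().any():
        raise ValueError("encode expects no missing values; impute first")
    enc = ClinicalEncoder(label_col=label_col)
    X = enc.fit(table).transform(table)
    y = table[label_col].copy() if label_col in table.columns else pd.Series(index=table.index, dtype=object)
    return X, y


# ---------------------------------------------------------------------------
# ADASYN


@dataclass(frozen=True)
class AdasynConfig:
    """ADASYN settings: neighbourhood size k, balance level beta, target class."""

    target_class: object
    k: int = 5
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")


class Adasyn(BaseEstimator):
    """Adaptive synthetic oversampling of one minority class.

    The algorithm, implemented from its defining equations:

    1. ``G = (n_maj - n_min) * beta`` synthetic samples in total, where
       ``n_maj`` is the largest class count;
    2. for each minority point, ``eta_i`` = fraction of non-minority
       samples among its k nearest neighbours *in the entire dataset*;
    3. ``r_i = eta_i / sum(eta)`` (uniform if every neighbourhood is pure);
    4. ``g_i = round(r_i * G)`` per point (half-up), then adjusted on the
       largest-``r_i`` points so the counts total exactly G;
    5. each synthetic point interpolates ``x_i + delta * (x_z - x_i)``
       toward a random one of the point's k nearest *minority* neighbours,
       with ``delta ~ U(0, 1)``.

    Neighbour search uses Euclidean distance on features min-max scaled to
    [0, 1]; interpolation happens in the original feature space.  Original
    rows are preserved verbatim, synthetic rows are appended.
    """

    def __init__(self, target_class: object, k: int = 5, beta: float = 1.0, seed: int = 0):
        self.target_class = target_class
        self.k = k
        self.beta = beta
        self.seed = seed

    def _allocate(self, eta: np.ndarray, G: int) -> np.ndarray:
        """Per-point synthetic counts g_i summing exactly to G."""
        if eta.sum() > 0:
            r = eta / eta.sum()
        else:
            r = np.full(eta.shape, 1.0 / eta.size)
        g = _round_half_up(r * G).astype(int)
        order = np.argsort(-r, kind="stable")  # largest r_i first
        i = 0
        while g.sum() < G:
            g[order[i % len(order)]] += 1
            i += 1
        i = 0
        while g.sum() > G:
            j = order[i % len(order)]
            if g[j] > 0:
                g[j] -= 1
            i += 1
        self.r_ = r
        return g

    def fit_resample(self, X: pd.DataFrame | np.ndarray, y: Sequence,
                     delta: float | None = None) -> tuple[pd.DataFrame, pd.Series]:
        """Oversample; returns (X', y') with originals first, synthetics after.

        ``delta`` pins the interpolation coefficient (diagnostic use);
        by default it is drawn U(0, 1) per synthetic point.
        """
        cfg = AdasynConfig(self.target_class, self.k, self.beta, self.seed)
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y), index=X.index, name=LABEL_COL)
        arr = X.to_numpy(dtype=float)

        minority_idx = np.flatnonzero(y.to_numpy() == cfg.target_class)
        n_min = minority_idx.size
        counts = y.value_counts()
        if cfg.target_class not in counts.index:
            raise ValueError(f"target class {cfg.target_class!r} absent from y")
        n_maj = int(counts.max())
        if n_min < cfg.k + 1:
            raise ValueError(
                f"minority class {cfg.target_class!r} has {n_min} samples; "
                f"ADASYN with k={cfg.k} needs at least k+1"
            )
        if cfg.beta == 0.0:
            warnings.warn("beta=0: no synthetic samples generated", stacklevel=2)
            self.g_ = np.zeros(n_min, dtype=int)
            return X.copy(), y.copy()

        G = int(_round_half_up((n_maj - n_min) * cfg.beta))
        if G <= 0:
            self.g_ = np.zeros(n_min, dtype=int)
            return X.copy(), y.copy()

        # Scale to [0, 1] for the neighbour search only.
        lo, hi = arr.min(axis=0), arr.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        scaled = (arr - lo) / span

        nn_all = NearestNeighbors(n_neighbors=cfg.k + 1).fit(scaled)
        _, nbr = nn_all.kneighbors(scaled[minority_idx])
        eta = np.empty(n_min)
        is_min = y.to_numpy() == cfg.target_class
        for row, i in enumerate(minority_idx):
            others = [j for j in nbr[row] if j != i][: cfg.k]
            eta[row] = np.sum(~is_min[others]) / cfg.k

        g = self._allocate(eta, G)
        self.g_ = g

        min_scaled = scaled[minority_idx]
        k_min = min(cfg.k + 1, n_min)
        nn_min = NearestNeighbors(n_neighbors=k_min).fit(min_scaled)
        _, nbr_min = nn_min.kneighbors(min_scaled)

        rng = np.random.default_rng(cfg.seed)
        new_rows = []
        for row, gi in enumerate(g):
            if gi == 0:
                continue
            candidates = [j for j in nbr_min[row] if j != row][: cfg.k]
            xi = arr[minority_idx[row]]
            for _ in range(gi):
                z = candidates[rng.integers(len(candidates))]
                xz = arr[minority_idx[z]]
                d = rng.uniform() if delta is None else float(delta)
                new_rows.append(xi + d * (xz - xi))

        X_new = pd.DataFrame(new_rows, columns=X.columns)
        X_out = pd.concat([X.reset_index(drop=True), X_new], ignore_index=True)
        y_out = pd.concat(
            [y.reset_index(drop=True),
             pd.Series([cfg.target_class] * len(new_rows), name=y.name)],
            ignore_index=True,
        )
        return X_out, y_out


def adasyn(X: pd.DataFrame, y: Sequence, cfg: AdasynConfig,
           delta: float | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Functional form of :class:`Adasyn`."""
    sampler = Adasyn(cfg.target_class, cfg.k, cfg.beta, cfg.seed)
    return sampler.fit_resample(X, y, delta=delta)


# ---------------------------------------------------------------------------
# Splitting


@dataclass(frozen=True)
class SplitSpec:
    """Per-class (stratified) train/test split specification."""

    train_fraction: float = 0.70
    stratify_by: str = LABEL_COL
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must lie in (0, 1), got {self.train_fraction}")


def stratified_split(table: pd.DataFrame, spec: SplitSpec = SplitSpec()
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split per class: round(train_fraction * n) rows to train, rest to test.

    Deterministic given ``spec.seed``; train and test are disjoint and
    their union is the input.  Every class needs at least 2 rows.
    """
    if spec.stratify_by not in table.columns:
        raise KeyError(f"stratification column {spec.stratify_by!r} not in table")
    rng = np.random.default_rng(spec.seed)
    train_parts, test_parts = [], []
    for label, group in table.groupby(spec.stratify_by, sort=False):
        if len(group) < 2:
            raise ValueError(f"class {label!r} has only {len(group)} row(s); cannot split")
        perm = rng.permutation(len(group))
        n_train = int(_round_half_up(spec.train_fraction * len(group)))
        n_train = min(max(n_train, 1), len(group) - 1)
        train_parts.append(group.iloc[perm[:n_train]])
        test_parts.append(group.iloc[perm[n_train:]])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    return train, test
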