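"""Multiclass evaluation suite for the diagnostic benchmark.

Seven metrics, all reported as percentages: macro precision, macro
recall, macro F-score, Cohen's kappa (multiclass), Hamming loss, Matthews
correlation coefficient (Gorodkin's multiclass generalization) and
accuracy.  For single-label multiclass prediction the Hamming loss is the
error rate, so HL = 100 - accuracy holds identically.

Also provided: the overfitting-gap statistic
``(train - validation) / train * 100`` with its Yes / Mild / No status
bands, the balanced-vs-unbalanced absolute/percentage difference report,
and one-vs-rest ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "METRIC_NAMES",
    "ConfusionCounts",
    "MetricReport",
    "OverfitReport",
    "DiffReport",
    "confusion",
    "report",
    "overfit",
    "diff",
    "diff_table",
    "roc_auc",
]

#: Canonical metric order (the decision-matrix criterion order C1..C7).
METRIC_NAMES = ("precision", "recall", "f_score", "kappa", "hamming_loss", "mcc", "accuracy")


@dataclass
class ConfusionCounts:
    """Full confusion matrix plus derived one-vs-rest counts per class."""

    classes: tuple
    matrix: np.ndarray  # matrix[i, j] = #(true class i predicted as class j)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        k = len(self.classes)
        if self.matrix.shape != (k, k):
            raise ValueError(f"matrix shape {self.matrix.shape} does not match {k} classes")

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.n - self.tp - self.fp - self.fn


def confusion(y_true: Sequence, y_pred: Sequence, classes: Sequence | None = None) -> ConfusionCounts:
    """Tally the confusion matrix of two equal-length label vectors.

    ``classes`` fixes the class order (and vocabulary); by default the
    sorted union of observed labels is used.  Predictions outside the
    vocabulary raise.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(y_true) | set(y_pred)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class vocabulary: {sorted(map(str, unknown))}")
    matrix = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        matrix[index[t], index[p]] += 1
    return ConfusionCounts(classes, matrix)


@dataclass
class MetricReport:
    """The seven benchmark metrics, each on the 0-100 percentage scale.

    Values are stored at full precision; use :meth:`rounded` for display.
    ``degenerate_classes`` lists classes whose precision/recall/F term had
    an empty denominator (defined as 0).
    """

    precision: float
    recall: float
    f_score: float
    kappa: float
    hamming_loss: float
    mcc: float
    accuracy: float
    degenerate_classes: list = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series({m: getattr(self, m) for m in METRIC_NAMES})

    def rounded(self, ndigits: int = 3) -> pd.Series:
        return self.as_series().round(ndigits)


def report(counts: ConfusionCounts) -> MetricReport:
    """Compute the seven-metric report from confusion counts.

    Precision/recall/F are macro-averaged over classes; kappa is
    multiclass Cohen's kappa; MCC is Gorodkin's multiclass coefficient;
    Hamming loss is the per-sample misclassification fraction (= error
    rate for single-label prediction).
    """
    m = counts.matrix.astype(float)
    n = counts.n
    if n == 0:
        raise ValueError("empty confusion counts")
    tp, fp, fn = counts.tp.astype(float), counts.fp.astype(float), counts.fn.astype(float)

    degenerate = []
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_k = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec_k = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f_k = np.where(prec_k + rec_k > 0, 2 * prec_k * rec_k / (prec_k + rec_k), 0.0)
    for i, c in enumerate(counts.classes):
        if tp[i] + fp[i] == 0 or tp[i] + fn[i] == 0:
            degenerate.append(c)

    accuracy = m.trace() / n
    hamming = 1.0 - accuracy

    # Cohen's kappa: observed vs chance agreement from the marginals.
    row, col = m.sum(axis=1), m.sum(axis=0)
    p_o = accuracy
    p_e = float(row @ col) / n**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 0.0

    # Gorodkin's multiclass MCC.
    c, s = m.trace(), float(n)
    num = c * s - float(row @ col)
    den = np.sqrt((s**2 - float(col @ col)) * (s**2 - float(row @ row)))
    mcc = num / den if den > 0 else 0.0

    return MetricReport(
        precision=100.0 * prec_k.mean(),
        recall=100.0 * rec_k.mean(),
        f_score=100.0 * f_k.mean(),
        kappa=100.0 * kappa,
        hamming_loss=100.0 * hamming,
        mcc=100.0 * mcc,
        accuracy=100.0 * accuracy,
        degenerate_classes=degenerate,
    )


@dataclass
class OverfitReport:
    """Train-vs-validation gap as a percentage of the train score.

    Status bands: Yes (>= 10%), Mild (5-10%), No (< 5%).
    """

    train_mean: float
    validation_mean: float
    overfit_pct: float
    status: str


def overfit(train_mean: float, validation_mean: float) -> OverfitReport:
    """Overfitting percentage (train - validation) / train * 100, to 2 dp."""
    if train_mean <= 0:
        raise ValueError(f"train mean must be > 0, got {train_mean}")
    pct = round((train_mean - validation_mean) / train_mean * 100.0, 2)
    status = "Yes" if pct >= 10.0 else ("Mild" if pct >= 5.0 else "No")
    return OverfitReport(train_mean, validation_mean, pct, status)


@dataclass
class DiffReport:
    """Absolute (AD) and percentage (PD) balanced-vs-unbalanced differences.

    ``pd_pct`` entries are None where the unbalanced value is 0 (PD
    undefined); such metrics are listed in ``undefined``.
    """

    ad: dict[str, float]
    pd_pct: dict[str, float | None]
    undefined: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"AD": self.ad, "PD": self.pd_pct})


def diff(balanced: "MetricReport | Mapping[str, float]",
         unbalanced: "MetricReport | Mapping[str, float]") -> DiffReport:
    """AD = balanced - unbalanced and PD = AD / unbalanced * 100 per metric."""
    bal = balanced.as_series() if isinstance(balanced, MetricReport) else pd.Series(dict(balanced))
    unb = unbalanced.as_series() if isinstance(unbalanced, MetricReport) else pd.Series(dict(unbalanced))
    if set(bal.index) != set(unb.index):
        raise ValueError("balanced and unbalanced reports cover different metrics")
    ad, pd_pct, undefined = {}, {}, []
    for metric in bal.index:
        a = float(bal[metric] - unb[metric])
        ad[metric] = round(a, 3)
        if unb[metric] == 0:
            pd_pct[metric] = None
            undefined.append(metric)
        else:
            pd_pct[metric] = round(a / float(unb[metric]) * 100.0, 2)
    return DiffReport(ad, pd_pct, undefined)


def diff_table(balanced: pd.DataFrame, unbalanced: pd.DataFrame) -> pd.DataFrame:
    """Row-wise :func:`diff` over two model x metric tables (same shape)."""
    if list(balanced.index) != list(unbalanced.index) or list(balanced.columns) != list(unbalanced.columns):
        raise ValueError("tables must share models and metrics")
    out = {}
    for model in balanced.index:
        d = diff(balanced.loc[model], unbalanced.loc[model])
        for metric in balanced.columns:
            out.setdefault((metric, "AD"), {})[model] = d.ad[metric]
            out.setdefault((metric, "PD"), {})[model] = d.pd_pct[metric]
    return pd.DataFrame(out).loc[balanced.index]


def roc_auc(y_true: Sequence, class_scores: np.ndarray,
            classes: Sequence | None = None) -> tuple[dict, float]:
    """One-vs-rest ROC AUC per class plus the macro mean.

    ``class_scores`` is an (n, K) score matrix whose columns follow
    ``classes`` (default: sorted observed labels).  A truth vector with a
    single class has no defined AUC and raises.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(class_scores, dtype=float)
    if classes is None:
        classes = sorted(set(y_true))
    classes = list(classes)
    if len(set(y_true)) < 2:
        raise ValueError("AUC undefined for single-class truth")
    if scores.shape != (len(y_true), len(classes)):
        raise ValueError(f"score matrix shape {scores.shape} does not match "
                         f"({len(y_true)}, {len(classes)})")
    per_class = {}
    for j, c in enumerate(classes):
        onevsrest = (y_true == c).astype(int)
        if onevsrest.min() == onevsrest.max():
            per_class[c] = np.nan
            continue
        per_class[c] = float(roc_auc_score(onevsrest, scores[:, j]))
    vals = [v for v in per_class.values() if not np.isnan(v)]
    return per_class, float(np.mean(vals))
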