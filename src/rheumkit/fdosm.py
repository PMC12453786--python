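"""Fuzzy decision by opinion score method (FDOSM).

FDOSM ranks a set of alternatives (here: trained diagnostic classifiers)
evaluated on several criteria (here: performance metrics) by combining a
raw decision matrix with *expert* linguistic judgments.  The procedure has
three stages:

1. **Data input** — a decision matrix ``v_ij`` of m alternatives x n
   criteria, each criterion marked *benefit* (larger is better), *cost*
   (smaller is better) or *critical* (closest to a stated target is best).
   The per-criterion ideal solution is the column max / min / nearest-to-
   target respectively.
2. **Transformation** — an expert compares every cell against its
   criterion's ideal and records one of five ordered linguistic terms:
   ND < SD < D < BD < HD (no / slight / - / big / huge difference).  The
   result is one opinion matrix per expert.  Opinions are *inputs* to this
   module, never computed from the numbers (see :func:`suggest_opinions`
   for a non-normative helper).
3. **Processing** — each term is replaced by a triangular fuzzy number
   (V1, V2, V3), defuzzified as S = (V1 + V2 + V3) / 3, aggregated across
   criteria, and ranked; the *lowest* score (closest to "no difference
   from ideal" on every criterion) wins.  Per-expert rankings are merged
   into a group decision by the arithmetic mean of the per-expert scores.

Two cross-criterion aggregation modes exist in the literature this method
derives from: ``mean`` (average of the per-criterion fuzzy means — the
default, used for the headline group ranking) and ``sum`` (their total).
Rounding conventions differ between the two modes and are chosen to match
the published arithmetic of each; see :func:`fuzzy_scores`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TERMS",
    "TFMScale",
    "DEFAULT_SCALE",
    "DecisionMatrix",
    "OpinionMatrix",
    "ScoreTable",
    "FdosmReport",
    "ideal_solution",
    "load_opinions",
    "fuzzy_scores",
    "rank",
    "group_decision",
    "run_fdosm",
    "suggest_opinions",
]

#: The five linguistic terms, in increasing order of difference from ideal.
TERMS: tuple[str, ...] = ("ND", "SD", "D", "BD", "HD")

_DIRECTIONS = ("benefit", "cost", "critical")


def _round4(x: float) -> float:
    """Round half-up to 4 decimals (decimal, not binary-float, semantics)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TFMScale:
    """Mapping from linguistic term to a triangular fuzzy number (V1, V2, V3)."""

    mapping: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for term in TERMS:
            if term not in self.mapping:
                raise ValueError(f"scale is missing term {term!r}")
        for term, (v1, v2, v3) in self.mapping.items():
            if not (v1 <= v2 <= v3):
                raise ValueError(f"TFM for {term!r} must satisfy V1 <= V2 <= V3, got {(v1, v2, v3)}")

    def fuzzy_mean(self, term: str) -> float:
        """Defuzzified value (V1 + V2 + V3) / 3 of a term, at full precision."""
        v1, v2, v3 = self.mapping[term]
        return (v1 + v2 + v3) / 3.0


#: Standard five-term scale used throughout.
DEFAULT_SCALE = TFMScale(
    {
        "ND": (0.0, 0.10, 0.30),
        "SD": (0.10, 0.30, 0.50),
        "D": (0.30, 0.50, 0.75),
        "BD": (0.50, 0.75, 0.90),
        "HD": (0.75, 0.90, 1.00),
    }
)


@dataclass
class DecisionMatrix:
    """Alternatives x criteria matrix of raw performance values.

    Parameters
    ----------
    data:
        DataFrame indexed by alternative name with one column per criterion.
    directions:
        Per-criterion direction: ``benefit``, ``cost`` or ``critical``.
        Criteria not listed default to ``benefit``.
    critical_targets:
        Target value per ``critical`` criterion (the ideal is the cell
        closest to the target).
    """

    data: pd.DataFrame
    directions: Mapping[str, str] = field(default_factory=dict)
    critical_targets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data).astype(float)
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("decision matrix needs at least one alternative and one criterion")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("decision matrix contains non-finite values")
        directions = dict(self.directions)
        for crit, direction in directions.items():
            if direction not in _DIRECTIONS:
                raise ValueError(f"unknown direction {direction!r} for criterion {crit!r}")
            if crit not in self.data.columns:
                raise ValueError(f"direction given for unknown criterion {crit!r}")
            if direction == "critical" and crit not in self.critical_targets:
                raise ValueError(f"critical criterion {crit!r} needs a target value")
        self.directions = {c: directions.get(c, "benefit") for c in self.data.columns}

    @property
    def alternatives(self) -> list[str]:
        return list(self.data.index)

    @property
    def criteria(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_csv(cls, path: str | Path, directions: str | Path | Mapping[str, str] | None = None,
                 critical_targets: Mapping[str, float] | None = None) -> "DecisionMatrix":
        """Read a decision matrix CSV (first column = alternative names).

        ``directions`` may be a mapping or the path of a JSON sidecar
        ``{criterion: direction}``.
        """
        df = pd.read_csv(path, index_col=0)
        if isinstance(directions, (str, Path)):
            directions = json.loads(Path(directions).read_text())
        return cls(df, directions or {}, critical_targets or {})

    def to_csv(self, path: str | Path, directions_path: str | Path | None = None) -> None:
        self.data.to_csv(path)
        if directions_path is not None:
            Path(directions_path).write_text(json.dumps(dict(self.directions), indent=1))


def ideal_solution(dm: DecisionMatrix) -> pd.DataFrame:
    """Per-criterion ideal value A* and the first alternative attaining it.

    benefit -> column max; cost -> column min; critical -> value closest to
    the criterion's target (ties broken by first-listed alternative; scoring
    downstream is unaffected by the tie-break since tied cells would carry
    identical opinions).
    """
    rows = {}
    for crit in dm.criteria:
        col = dm.data[crit]
        if col.empty:
            raise ValueError(f"criterion {crit!r} has no values")
        direction = dm.directions[crit]
        if direction == "benefit":
            idx = col.idxmax()
        elif direction == "cost":
            idx = col.idxmin()
        else:
            idx = (col - dm.critical_targets[crit]).abs().idxmin()
        rows[crit] = {"ideal": col.loc[idx], "alternative": idx, "direction": direction}
    return pd.DataFrame(rows).T


@dataclass
class OpinionMatrix:
    """One expert's grid of linguistic terms, aligned to a decision matrix."""

    terms: pd.DataFrame
    expert: str = "expert"

    def __post_init__(self) -> None:
        self.terms = pd.DataFrame(self.terms)
        bad = [
            (i, j)
            for i in self.terms.index
            for j in self.terms.columns
            if self.terms.loc[i, j] not in TERMS
        ]
        if bad:
            i, j = bad[0]
            raise ValueError(
                f"unknown linguistic term {self.terms.loc[i, j]!r} at "
                f"(alternative={i!r}, criterion={j!r}); valid terms: {TERMS}"
            )

    @property
    def alternatives(self) -> list[str]:
        return list(self.terms.index)


def load_opinions(source: str | Path | pd.DataFrame, expert: str | None = None,
                  dm: DecisionMatrix | None = None) -> OpinionMatrix:
    """Load and validate an expert opinion matrix (CSV or DataFrame).

    If ``dm`` is given, the shape must match and the cell of each
    criterion's ideal alternative is checked to be ND (a warning, not an
    error — experts occasionally grade near-ties as slight differences).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        name = expert or "expert"
    else:
        df = pd.read_csv(source, index_col=0)
        name = expert or Path(source).stem
    om = OpinionMatrix(df, expert=name)
    if dm is not None:
        if list(df.index) != dm.alternatives or list(df.columns) != dm.criteria:
            raise ValueError(
                f"opinion matrix of {name!r} does not align with the decision matrix "
                f"(expected {len(dm.alternatives)}x{len(dm.criteria)})"
            )
        ideals = ideal_solution(dm)
        for crit in dm.criteria:
            best = ideals.loc[crit, "alternative"]
            if df.loc[best, crit] != "ND":
                warnings.warn(
                    f"expert {name!r} graded the ideal alternative {best!r} of criterion "
                    f"{crit!r} as {df.loc[best, crit]!r} (expected ND)",
                    stacklevel=2,
                )
    return om


@dataclass
class ScoreTable:
    """Per-alternative fuzzy scores S(A) and (optionally) ranks."""

    scores: pd.Series
    ranks: pd.Series | None = None
    context: str = "per-expert"
    aggregation: str = "mean"
    expert: str | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"score": self.scores})
        if self.ranks is not None:
            out["rank"] = self.ranks
        return out


def fuzzy_scores(op: OpinionMatrix, scale: TFMScale = DEFAULT_SCALE,
                 aggregation: str = "mean") -> ScoreTable:
    """Convert one opinion matrix into per-alternative fuzzy scores.

    Each cell's term becomes its defuzzified triangular mean
    ``(V1 + V2 + V3) / 3``; the per-criterion values are then aggregated
    across criteria:

    - ``mean``: arithmetic mean of the full-precision per-criterion values,
      reported to 4 decimals.  This is the group-ranking convention.
    - ``sum``: per-criterion values are first rounded to 4 decimals, then
      summed — the convention of the published worked example, whose
      arithmetic carries 4-decimal intermediate values (e.g. two D terms
      give 2 x 0.5167 = 1.0334, not 3.1/3 = 1.0333...).
    """
    if aggregation not in ("mean", "sum"):
        raise ValueError(f"aggregation must be 'mean' or 'sum', got {aggregation!r}")
    per_criterion = op.terms.map(scale.fuzzy_mean)
    if aggregation == "mean":
        scores = per_criterion.mean(axis=1)
    else:
        scores = per_criterion.map(_round4).sum(axis=1)
    scores = scores.map(_round4)
    scores.name = "score"
    return ScoreTable(scores, context="per-expert", aggregation=aggregation, expert=op.expert)


def rank(scores: ScoreTable) -> ScoreTable:
    """Competition-rank the scores: R_i = 1 + #{j : S_j < S_i}; lowest wins.

    Ties share the smallest applicable rank.
    """
    s = scores.scores.to_numpy()
    ranks = pd.Series(
        [1 + int((s < si).sum()) for si in s], index=scores.scores.index, name="rank"
    )
    return ScoreTable(scores.scores, ranks, scores.context, scores.aggregation, scores.expert)


def group_decision(per_expert: Sequence[ScoreTable]) -> ScoreTable:
    """Aggregate expert score tables into a final group ranking.

    The group score of each alternative is the arithmetic mean of its
    (4-decimal) per-expert scores, itself rounded to 4 decimals, then
    ranked.  All tables must cover the same alternatives.
    """
    if len(per_expert) == 0:
        raise ValueError("need at least one expert score table")
    base = list(per_expert[0].scores.index)
    for st in per_expert[1:]:
        if list(st.scores.index) != base:
            raise ValueError("expert score tables cover different alternatives")
    stacked = pd.concat([st.scores for st in per_expert], axis=1)
    scores = stacked.mean(axis=1).map(_round4)
    scores.name = "score"
    return rank(ScoreTable(scores, context="group", aggregation=per_expert[0].aggregation))


@dataclass
class FdosmReport:
    """Full output of an FDOSM run: provenance plus all score tables."""

    ideal: pd.DataFrame
    per_expert: list[ScoreTable]
    group: ScoreTable

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: one score/rank column pair per expert plus the final decision."""
        out = {}
        for st in self.per_expert:
            ranked = rank(st) if st.ranks is None else st
            out[f"{st.expert} score"] = ranked.scores
            out[f"{st.expert} rank"] = ranked.ranks
        out["final score"] = self.group.scores
        out["final rank"] = self.group.ranks
        return pd.DataFrame(out)


def run_fdosm(dm: DecisionMatrix, opinions: Iterable[OpinionMatrix | pd.DataFrame | str | Path],
              scale: TFMScale = DEFAULT_SCALE, aggregation: str = "mean") -> FdosmReport:
    """End-to-end FDOSM: ideal solutions, per-expert scores/ranks, group decision."""
    oms = []
    for k, op in enumerate(opinions, start=1):
        if not isinstance(op, OpinionMatrix):
            op = load_opinions(op, expert=f"expert{k}", dm=dm)
        elif list(op.terms.index) != dm.alternatives or list(op.terms.columns) != dm.criteria:
            raise ValueError(f"opinion matrix of {op.expert!r} does not align with the decision matrix")
        oms.append(op)
    if not oms:
        raise ValueError("need at least one opinion matrix")
    per_expert = [rank(fuzzy_scores(om, scale, aggregation)) for om in oms]
    return FdosmReport(ideal_solution(dm), per_expert, group_decision(per_expert))


def suggest_opinions(dm: DecisionMatrix, expert: str = "auto",
                     cuts: tuple[float, float, float, float] = (0.02, 0.10, 0.25, 0.50)) -> OpinionMatrix:
    """Demo helper: derive linguistic terms from relative gaps to the ideal.

    This mapping is an invented convenience for demonstrations and tests —
    in the method proper the value-to-term judgment belongs to a human
    expert.  The relative gap |v - ideal| / range(criterion) is bucketed at
    ``cuts`` into ND / SD / D / BD / HD.
    """
    ideals = ideal_solution(dm)
    terms = {}
    for crit in dm.criteria:
        col = dm.data[crit]
        spread = float(col.max() - col.min()) or 1.0
        gap = (col - ideals.loc[crit, "ideal"]).abs() / spread
        terms[crit] = pd.cut(
            gap, bins=[-np.inf, *cuts, np.inf], labels=TERMS
        ).astype(str)
    return OpinionMatrix(pd.DataFrame(terms, index=dm.data.index)[dm.criteria], expert=expert)
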