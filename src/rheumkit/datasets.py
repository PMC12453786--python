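"""Loaders for the shipped reference fixtures.

The package ships the published reference tables it can legitimately
recompute from: the two 12-model decision matrices (unbalanced and
ADASYN-balanced runs), three expert opinion matrices, the 5-fold CV
train/validation score tables, and the small 3-model worked example with
its single-expert opinion grid.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .fdosm import DecisionMatrix, OpinionMatrix, load_opinions

_DATA = Path(__file__).parent / "data"

__all__ = [
    "load_diagnostic_dm",
    "load_expert_opinions",
    "load_example_dm",
    "load_example_opinion",
    "load_cv_scores",
]


def load_diagnostic_dm(balanced: bool = True) -> DecisionMatrix:
    """The 12-model x 7-criterion decision matrix (benefit everywhere except
    Hamming loss, which is a cost criterion)."""
    which = "balanced" if balanced else "unbalanced"
    return DecisionMatrix.from_csv(
        _DATA / f"diagnostic_dm_{which}.csv", _DATA / "diagnostic_dm_directions.json"
    )


def load_expert_opinions(dm: DecisionMatrix | None = None) -> list[OpinionMatrix]:
    """The three expert linguistic opinion matrices over the 12-model panel."""
    return [
        load_opinions(_DATA / f"expert{k}.csv", expert=f"Expert {k}", dm=dm)
        for k in (1, 2, 3)
    ]


def load_example_dm() -> DecisionMatrix:
    """The 3-model, 2-criterion walkthrough decision matrix."""
    return DecisionMatrix.from_csv(
        _DATA / "example_dm.csv", {"Precision": "benefit", "Accuracy": "benefit"}
    )


def load_example_opinion() -> OpinionMatrix:
    """The single-expert opinion grid of the walkthrough example."""
    return load_opinions(_DATA / "example_opinion.csv", expert="Expert")


def load_cv_scores(balanced: bool = False) -> pd.DataFrame:
    """Published 5-fold CV train/validation accuracy means per model."""
    which = "balanced" if balanced else "unbalanced"
    return pd.read_csv(_DATA / f"cv_scores_{which}.csv", index_col=0)
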