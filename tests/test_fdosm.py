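"""FDOSM: ideal solutions, fuzzy scoring, ranking, group aggregation.

Includes the exact reproduction of the published three-expert benchmark
ranking (36 per-expert + 12 final scores, all to 4 decimals) and seeded
property tests of the method's invariants.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rheumkit.datasets import (
    load_diagnostic_dm,
    load_example_dm,
    load_example_opinion,
    load_expert_opinions,
)
from rheumkit.fdosm import (
    DEFAULT_SCALE,
    TERMS,
    DecisionMatrix,
    OpinionMatrix,
    ScoreTable,
    TFMScale,
    fuzzy_scores,
    group_decision,
    ideal_solution,
    load_opinions,
    rank,
    run_fdosm,
    suggest_opinions,
)

#: Published per-expert and final (score, rank) pairs for the 12-model panel.
PUBLISHED = {
    "XGBoost": (0.2286, 4, 0.1810, 3, 0.2048, 4, 0.2048, 4),
    "KNN": (0.6595, 10, 0.5738, 10, 0.6881, 11, 0.6405, 10),
    "DT": (0.3071, 6, 0.2524, 6, 0.2762, 6, 0.2786, 6),
    "RF": (0.1571, 2, 0.1571, 2, 0.1571, 2, 0.1571, 2),
    "SVM": (0.5429, 9, 0.4548, 9, 0.5119, 9, 0.5032, 9),
    "ANN": (0.3357, 7, 0.2762, 7, 0.3071, 7, 0.3063, 7),
    "SGD": (0.4857, 8, 0.3929, 8, 0.4238, 8, 0.4341, 8),
    "GBoost": (0.1333, 1, 0.1333, 1, 0.1333, 1, 0.1333, 1),
    "LGBM": (0.2048, 3, 0.2048, 4, 0.1810, 3, 0.1969, 3),
    "AdaBoost": (0.8833, 12, 0.8833, 12, 0.8833, 12, 0.8833, 12),
    "NB": (0.6881, 11, 0.6286, 11, 0.6595, 10, 0.6587, 11),
    "ET": (0.2595, 5, 0.2286, 5, 0.2286, 5, 0.2389, 5),
}


def random_opinion(rng, m=None, n=None):
    m = m or int(rng.integers(2, 8))
    n = n or int(rng.integers(1, 6))
    grid = rng.choice(TERMS, size=(m, n))
    return OpinionMatrix(
        pd.DataFrame(grid, index=[f"A{i}" for i in range(m)],
                     columns=[f"C{j}" for j in range(n)])
    )


class TestIdealSolution:
    def test_example_benefit_maxima(self):
        ideals = ideal_solution(load_example_dm())
        assert ideals.loc["Precision", "ideal"] == 83.6
        assert ideals.loc["Accuracy", "ideal"] == 82.9
        assert ideals.loc["Precision", "alternative"] == "A3"

    def test_cost_column_minimum(self):
        dm = DecisionMatrix(pd.DataFrame({"c": [0.1, 0.2]}, index=["A", "B"]),
                            {"c": "cost"})
        assert ideal_solution(dm).loc["c", "ideal"] == 0.1

    def test_critical_nearest_to_target(self):
        dm = DecisionMatrix(pd.DataFrame({"c": [30.0, 49.0, 80.0]}, index=list("ABC")),
                            {"c": "critical"}, {"c": 50.0})
        assert ideal_solution(dm).loc["c", "ideal"] == 49.0

    def test_critical_without_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            DecisionMatrix(pd.DataFrame({"c": [1.0]}), {"c": "critical"})


class TestLoadOpinions:
    def test_shipped_expert_grid(self):
        dm = load_diagnostic_dm(balanced=True)
        om = load_expert_opinions(dm=dm)[0]
        assert om.terms.shape == (12, 7)
        assert (om.terms.loc["GBoost"] == "ND").all()

    def test_single_cell_grid(self):
        om = load_opinions(pd.DataFrame({"C1": ["ND"]}, index=["A"]))
        assert om.terms.loc["A", "C1"] == "ND"

    def test_unknown_symbol_located(self):
        grid = pd.DataFrame({"C1": ["ND", "XX"]}, index=["A", "B"])
        with pytest.raises(ValueError, match="'XX'.*'B'.*'C1'"):
            load_opinions(grid)

    def test_non_nd_ideal_cell_warns(self):
        dm = DecisionMatrix(pd.DataFrame({"C1": [2.0, 1.0]}, index=["A", "B"]))
        grid = pd.DataFrame({"C1": ["SD", "HD"]}, index=["A", "B"])
        with pytest.warns(UserWarning, match="ideal"):
            load_opinions(grid, dm=dm)

    def test_misaligned_shape_rejected(self):
        dm = load_example_dm()
        grid = pd.DataFrame({"Precision": ["ND"]}, index=["A1"])
        with pytest.raises(ValueError, match="align"):
            load_opinions(grid, dm=dm)


class TestFuzzyScores:
    def test_all_nd_row_mean_mode(self):
        om = load_opinions(pd.DataFrame([["ND"] * 7], index=["A"], columns=list("abcdefg")))
        assert fuzzy_scores(om).scores["A"] == 0.1333

    def test_all_hd_row_mean_mode(self):
        om = load_opinions(pd.DataFrame([["HD"] * 4], index=["A"], columns=list("abcd")))
        assert fuzzy_scores(om).scores["A"] == 0.8833

    def test_worked_example_sum_mode(self):
        st_table = fuzzy_scores(load_example_opinion(), aggregation="sum")
        assert st_table.scores["A1"] == 1.0334
        assert st_table.scores["A2"] == 1.4334
        assert st_table.scores["A3"] == 0.2666

    def test_six_nd_one_sd_row(self):
        om = load_opinions(pd.DataFrame([["ND"] * 6 + ["SD"]], index=["RF"],
                                        columns=list("abcdefg")))
        assert fuzzy_scores(om).scores["RF"] == 0.1571

    def test_invalid_aggregation_rejected(self):
        with pytest.raises(ValueError, match="aggregation"):
            fuzzy_scores(load_example_opinion(), aggregation="median")


class TestRank:
    def test_worked_example_ranks(self):
        ranked = rank(fuzzy_scores(load_example_opinion(), aggregation="sum"))
        assert ranked.ranks.tolist() == [2, 3, 1]

    def test_ties_share_lowest_rank(self):
        ranked = rank(ScoreTable(pd.Series({"A": 0.5, "B": 0.5})))
        assert ranked.ranks.tolist() == [1, 1]

    def test_distinct_scores_rank_as_permutation(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            m = int(rng.integers(2, 12))
            scores = pd.Series(rng.permutation(m).astype(float),
                               index=[f"A{i}" for i in range(m)])
            ranked = rank(ScoreTable(scores))
            assert sorted(ranked.ranks) == list(range(1, m + 1))
            assert ranked.ranks[scores.idxmin()] == 1


class TestGroupDecision:
    def test_published_group_scores(self):
        tables = [fuzzy_scores(om) for om in load_expert_opinions()]
        group = group_decision(tables)
        assert group.scores["XGBoost"] == 0.2048
        assert group.scores["KNN"] == 0.6405

    def test_single_expert_is_identity(self):
        table = fuzzy_scores(load_expert_opinions()[0])
        group = group_decision([table])
        pd.testing.assert_series_equal(group.scores, table.scores)

    def test_alternative_mismatch_rejected(self):
        a = ScoreTable(pd.Series({"A": 0.1, "B": 0.2}))
        b = ScoreTable(pd.Series({"A": 0.1, "C": 0.2}))
        with pytest.raises(ValueError, match="different alternatives"):
            group_decision([a, b])


class TestFullReproduction:
    def test_all_published_scores_and_ranks(self):
        dm = load_diagnostic_dm(balanced=True)
        result = run_fdosm(dm, load_expert_opinions(dm=dm))
        wide = result.to_frame()
        for model, row in PUBLISHED.items():
            got = []
            for k in (1, 2, 3):
                got += [wide.loc[model, f"Expert {k} score"], wide.loc[model, f"Expert {k} rank"]]
            got += [wide.loc[model, "final score"], wide.loc[model, "final rank"]]
            assert got[0::2] == pytest.approx(list(row[0::2]), abs=5e-5), model
            assert got[1::2] == list(row[1::2]), model

    def test_single_alternative_always_first(self):
        dm = DecisionMatrix(pd.DataFrame({"C1": [5.0]}, index=["A"]))
        om = OpinionMatrix(pd.DataFrame({"C1": ["BD"]}, index=["A"]))
        result = run_fdosm(dm, [om])
        assert result.group.ranks["A"] == 1

    def test_row_permutation_equivariance(self):
        dm = load_diagnostic_dm(balanced=True)
        oms = load_expert_opinions(dm=dm)
        base = run_fdosm(dm, oms).group
        order = list(reversed(dm.alternatives))
        dm_p = DecisionMatrix(dm.data.loc[order], dm.directions)
        oms_p = [OpinionMatrix(om.terms.loc[order], om.expert) for om in oms]
        permuted = run_fdosm(dm_p, oms_p).group
        pd.testing.assert_series_equal(base.scores.loc[order], permuted.scores)
        pd.testing.assert_series_equal(base.ranks.loc[order], permuted.ranks)


class TestInvariants:
    @given(st.integers(0, 2**31 - 1), st.booleans())
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_monotone_under_term_escalation(self, seed, use_sum):
        rng = np.random.default_rng(seed)
        om = random_opinion(rng)
        agg = "sum" if use_sum else "mean"
        base = fuzzy_scores(om, aggregation=agg).scores
        i = om.terms.index[rng.integers(om.terms.shape[0])]
        j = om.terms.columns[rng.integers(om.terms.shape[1])]
        level = TERMS.index(om.terms.loc[i, j])
        if level == len(TERMS) - 1:
            return
        bumped = om.terms.copy()
        bumped.loc[i, j] = TERMS[level + 1]
        new = fuzzy_scores(OpinionMatrix(bumped), aggregation=agg).scores
        assert new[i] >= base[i]
        others = [a for a in om.terms.index if a != i]
        assert (new[others] == base[others]).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_mean_mode_score_bounds(self, seed):
        om = random_opinion(np.random.default_rng(seed))
        scores = fuzzy_scores(om).scores
        assert (scores >= 0.1333).all() and (scores <= 0.8833).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_ranks_are_valid_competition_ranks(self, seed):
        om = random_opinion(np.random.default_rng(seed))
        ranked = rank(fuzzy_scores(om))
        s, r = ranked.scores, ranked.ranks
        for a in s.index:
            assert r[a] == 1 + int((s < s[a]).sum())

    def test_uniform_opinion_matrix_all_rank_one(self):
        for term in TERMS:
            om = OpinionMatrix(pd.DataFrame([[term] * 3] * 4,
                                            index=list("ABCD"), columns=list("xyz")))
            ranked = rank(fuzzy_scores(om))
            assert ranked.scores.nunique() == 1
            assert (ranked.ranks == 1).all()


class TestScale:
    def test_default_scale_values(self):
        assert DEFAULT_SCALE.mapping["ND"] == (0.0, 0.10, 0.30)
        assert DEFAULT_SCALE.mapping["HD"] == (0.75, 0.90, 1.00)

    def test_disordered_triple_rejected(self):
        bad = dict(DEFAULT_SCALE.mapping)
        bad["D"] = (0.8, 0.5, 0.9)
        with pytest.raises(ValueError, match="V1 <= V2 <= V3"):
            TFMScale(bad)

    def test_missing_term_rejected(self):
        with pytest.raises(ValueError, match="missing term"):
            TFMScale({"ND": (0, 0.1, 0.3)})


class TestSuggestOpinions:
    def test_ideal_rows_get_nd(self):
        dm = load_example_dm()
        om = suggest_opinions(dm)
        assert (om.terms.loc["A3"] == "ND").all()

    def test_terms_are_valid(self):
        om = suggest_opinions(load_diagnostic_dm(balanced=True))
        assert om.terms.isin(TERMS).all().all()
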