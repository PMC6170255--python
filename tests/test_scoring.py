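"""The selectivity score: components, worked values, invariants, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinoselect import (
    InhibitionMatrix,
    TargetSet,
    UndefinedScoreError,
    ValidationError,
    broad_penalty,
    inhibition_score,
    near_penalty,
    rank_compounds,
    selectivity_score,
    significant_off_targets,
)
from conftest import naive_score, random_row


def make_row(targets: dict, offtargets: dict) -> pd.Series:
    return pd.Series({**targets, **offtargets}, dtype=float)


class TestTargetSet:
    def test_cap_at_ten(self):
        TargetSet([f"K{i}" for i in range(10)])  # ok
        with pytest.raises(ValidationError, match="10-target"):
            TargetSet([f"K{i}" for i in range(11)])

    def test_cap_overridable(self):
        ts = TargetSet([f"K{i}" for i in range(11)], max_targets=20)
        assert len(ts) == 11

    def test_duplicates_and_empty_rejected(self):
        with pytest.raises(ValidationError):
            TargetSet(["A", "A"])
        with pytest.raises(ValidationError):
            TargetSet([])


class TestInhibitionScore:
    def test_single_target_identity(self):
        row = make_row({"A": 80}, {"B": 10})
        assert inhibition_score(row, TargetSet(["A"])) == 80.0

    def test_geometric_mean_of_two(self):
        row = make_row({"A": 81, "B": 100}, {"C": 0})
        assert inhibition_score(row, TargetSet(["A", "B"])) == pytest.approx(90.0)

    def test_zero_target_annihilates(self):
        row = make_row({"A": 0, "B": 100}, {"C": 0})
        assert inhibition_score(row, TargetSet(["A", "B"])) == 0.0

    def test_missing_target_excluded_from_mean(self):
        row = make_row({"A": 64, "B": np.nan}, {"C": 0})
        assert inhibition_score(row, TargetSet(["A", "B"])) == 64.0

    def test_no_measured_target_raises(self):
        row = make_row({"A": np.nan}, {"B": 10})
        with pytest.raises(UndefinedScoreError):
            inhibition_score(row, TargetSet(["A"]))

    def test_target_absent_from_panel_raises(self):
        row = make_row({"A": 80}, {"B": 10})
        with pytest.raises(ValidationError, match="GHOST"):
            inhibition_score(row, TargetSet(["GHOST"]))


class TestPenalties:
    def test_broad_is_mean_of_offtargets(self):
        row = make_row({"A": 80}, {"B": 40, "C": 20})
        assert broad_penalty(row, TargetSet(["A"])) == 30.0

    def test_zero_profile_gives_zero_penalties(self):
        row = make_row({"A": 80}, {f"K{i}": 0 for i in range(20)})
        ts = TargetSet(["A"])
        assert broad_penalty(row, ts) == 0.0
        assert near_penalty(row, ts, 80.0) == 0.0

    def test_near_penalty_worked_value(self):
        # (1/2)(40*40/120 + 20*20/100) = 8.6667
        row = make_row({"A": 80}, {"B": 40, "C": 20})
        assert near_penalty(row, TargetSet(["A"]), 80.0) == pytest.approx(26 / 3)

    def test_near_penalty_strong_offtarget_weak_target(self):
        # single off-target 90 against G=10 is punished near full magnitude
        row = make_row({"A": 10}, {"B": 90})
        assert near_penalty(row, TargetSet(["A"]), 10.0) == pytest.approx(81.0)

    def test_zero_offtarget_contributes_zero_even_when_g_zero(self):
        row = make_row({"A": 0}, {"B": 0, "C": 50})
        # only the 50 term: 50*50/50 = 50, averaged over M=2
        assert near_penalty(row, TargetSet(["A"]), 0.0) == pytest.approx(25.0)


class TestSelectivityScore:
    def test_perfectly_selective_compound_scores_100(self):
        row = make_row({"A": 100}, {f"K{i}": 0 for i in range(10)})
        rec = selectivity_score(row, TargetSet(["A"]))
        assert rec.selectivity_score == 100.0
        assert rec.penalty_broad == rec.penalty_near == 0.0

    def test_worked_composite_value(self):
        row = make_row({"A": 80}, {"B": 40, "C": 20})
        rec = selectivity_score(row, TargetSet(["A"]))
        assert rec.selectivity_score == pytest.approx(80 - 30 - 26 / 3)

    def test_pan_weak_composite_value(self):
        # target 80, 100 off-targets all at 10: S = 80 - 10 - 10*10/90
        row = make_row({"A": 80}, {f"K{i}": 10 for i in range(100)})
        rec = selectivity_score(row, TargetSet(["A"]))
        assert rec.selectivity_score == pytest.approx(80 - 10 - 100 / 90)

    def test_missing_cells_excluded_from_m(self):
        row = make_row({"A": 80}, {"B": 40, "C": np.nan})
        rec = selectivity_score(row, TargetSet(["A"]))
        assert rec.n_offtargets_measured == 1
        assert rec.penalty_broad == 40.0

    def test_undefined_when_no_target_measured(self):
        row = make_row({"A": np.nan}, {"B": 10})
        rec = selectivity_score(row, TargetSet(["A"]))
        assert not rec.defined
        assert np.isnan(rec.selectivity_score)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_oracle_on_random_rows(self, seed):
        """Implementation agrees with a plain-loop evaluation to 1e-9."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        row = random_row(rng, n)
        n_targets = int(rng.integers(1, min(3, n - 1) + 1))
        targets = TargetSet(row.index[:n_targets])
        tvals = [row[k] for k in targets if np.isfinite(row[k])]
        offs = [v for k, v in row.items() if k not in set(targets) and np.isfinite(v)]
        rec = selectivity_score(row, targets)
        if not tvals:
            assert not rec.defined
            return
        expected = naive_score(tvals, offs)
        assert rec.inhibition_score == pytest.approx(expected["G"], abs=1e-9)
        assert rec.penalty_broad == pytest.approx(expected["P_b"], abs=1e-9)
        assert rec.penalty_near == pytest.approx(expected["P_n"], abs=1e-9)
        assert rec.selectivity_score == pytest.approx(expected["S"], abs=1e-9)


class TestScoreInvariants:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_target_score(self, seed):
        """S <= G <= 100 for every scored row."""
        rng = np.random.default_rng(seed)
        row = random_row(rng, int(rng.integers(3, 12)))
        rec = selectivity_score(row, TargetSet([row.index[0]]))
        if rec.defined:
            assert rec.selectivity_score <= rec.inhibition_score <= 100.0
            assert rec.selectivity_score >= -200.0

    def test_monotone_increasing_in_target(self):
        ts = TargetSet(["A"])
        offs = {"B": 40, "C": 20, "D": 70}
        scores = [
            selectivity_score(make_row({"A": g}, offs), ts).selectivity_score
            for g in [10, 30, 50, 70, 90]
        ]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_monotone_decreasing_in_offtarget(self):
        ts = TargetSet(["A"])
        scores = [
            selectivity_score(make_row({"A": 80}, {"B": v, "C": 20}), ts).selectivity_score
            for v in [0, 10, 30, 60, 100]
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_dominance_ordering(self, seed):
        """Higher targets and lower off-targets can never lower the score."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        kin = [f"K{i}" for i in range(n)]
        ts = TargetSet([kin[0]])
        base = rng.uniform(0, 100, size=n)
        better = base.copy()
        better[0] = min(100.0, base[0] + rng.uniform(0, 20))
        better[1:] = np.maximum(0.0, base[1:] - rng.uniform(0, 20, size=n - 1))
        s_base = selectivity_score(pd.Series(base, index=kin), ts).selectivity_score
        s_better = selectivity_score(pd.Series(better, index=kin), ts).selectivity_score
        assert s_better >= s_base - 1e-12


class TestSignificantOffTargets:
    def test_boundary_half_g_included(self):
        row = make_row({"A": 80}, {"B": 40, "C": 39, "D": 81})
        recs = significant_off_targets(row, TargetSet(["A"]))
        assert [r.kinase for r in recs] == ["D", "B"]  # descending inhibition
        assert recs[1].inhibition == 40.0
        assert recs[0].ratio == pytest.approx(81 / 80)

    def test_none_significant(self):
        row = make_row({"A": 80}, {"B": 39, "C": 10})
        assert significant_off_targets(row, TargetSet(["A"])) == []

    def test_zero_target_returns_any_inhibited(self):
        row = make_row({"A": 0}, {"B": 5, "C": 0})
        recs = significant_off_targets(row, TargetSet(["A"]))
        assert [r.kinase for r in recs] == ["B"]
        assert np.isnan(recs[0].ratio)

    def test_undefined_compound_raises(self):
        row = make_row({"A": np.nan}, {"B": 10})
        with pytest.raises(UndefinedScoreError):
            significant_off_targets(row, TargetSet(["A"]))


class TestRankCompounds:
    def test_dominant_compound_ranks_first(self):
        df = pd.DataFrame(
            {"T": [90.0, 90.0], "K1": [5.0, 50.0], "K2": [5.0, 50.0]},
            index=["dominant", "worse"],
        )
        ranked = rank_compounds(InhibitionMatrix(data=df), TargetSet(["T"]))
        assert ranked["compound_id"].tolist() == ["dominant", "worse"]

    def test_identical_rows_tiebreak_by_id(self):
        df = pd.DataFrame(
            {"T": [90.0, 90.0], "K1": [5.0, 5.0], "K2": [1.0, 1.0]},
            index=["zeta", "alpha"],
        )
        ranked = rank_compounds(InhibitionMatrix(data=df), TargetSet(["T"]))
        assert ranked["compound_id"].tolist() == ["alpha", "zeta"]

    def test_undefined_compounds_listed_last_and_flagged(self):
        df = pd.DataFrame(
            {"T": [90.0, np.nan], "K1": [5.0, 5.0], "K2": [1.0, 1.0]},
            index=["scored", "unscored"],
        )
        ranked = rank_compounds(InhibitionMatrix(data=df), TargetSet(["T"]))
        assert ranked["compound_id"].tolist() == ["scored", "unscored"]
        assert ranked["defined"].tolist() == [True, False]

    def test_absent_target_rejected_with_name(self, small_matrix):
        with pytest.raises(ValidationError, match="GHOST"):
            rank_compounds(small_matrix, TargetSet(["GHOST"]))

    def test_table_has_documented_columns(self, small_matrix):
        ranked = rank_compounds(small_matrix, TargetSet(["AKT1"]))
        assert ranked.columns.tolist() == [
            "compound_id", "inhibition_score", "penalty_broad", "penalty_near",
            "selectivity_score", "n_targets_measured", "n_offtargets_measured",
            "n_significant_offtargets", "defined",
        ]
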