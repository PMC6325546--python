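"""Reaction-time medians, group difference lists, ordering probability,
and rank-correlation analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tojlab.errors import DegenerateInputError, ParameterError
from tojlab.rt_analysis import (condition_rank_matrix, group_rt_differences,
                                ordering_probability, rank_correlations,
                                rt_condition_medians, rt_dprime_rank_table,
                                rt_medians)
from tojlab.sdt import dprime_frame
from tojlab.synthetic_data import CohortSpec, simulate_cohort, simulate_trials, sample_cohort
from tojlab.trial_model import ParticipantSet

from conftest import build_trials, perfect_chooser


def constant_rt_set(pid, group, rt):
    return build_trials(pid, group, perfect_chooser, rt=rt)


class TestRTMedians:
    def test_odd_count_median(self):
        frame = build_trials("p01", "brass", perfect_chooser,
                             rt_fn=lambda m, d, x, rep: [300, 400, 500][rep % 3])
        table = rt_medians(ParticipantSet.from_frame(frame))
        assert (table.participant_medians["median_rt_ms"] == 400).all()
        assert len(table.participant_medians) == 28

    def test_single_trial_per_cell_override(self):
        spec = CohortSpec(group_sizes={"brass": 1}, seed=5)
        obs = sample_cohort(spec)
        ps = simulate_trials(obs, seed=6, reps_per_cell=1)
        table = rt_medians(ps)
        merged = table.participant_medians.merge(
            ps.trials, on=["participant_id", "group", "motion_type",
                           "initial_directions", "asynchrony_ms"])
        assert np.allclose(merged["median_rt_ms"], merged["rt_ms"])

    def test_zero_asynchrony_penalty_recovered(self):
        spec = CohortSpec(group_sizes={"brass": 12}, rt_zero_penalty_ms=150.0,
                          seed=31)
        table = rt_medians(simulate_cohort(spec, trial_seed=32))
        grp = table.group_medians
        zero = grp[grp["asynchrony_ms"] == 0]["median_rt_ms"].median()
        nonzero = grp[grp["asynchrony_ms"] != 0]["median_rt_ms"].mean()
        assert zero - nonzero == pytest.approx(150.0, abs=25.0)


class TestGroupDifferences:
    def test_identical_groups_all_zero(self):
        frame = pd.concat([constant_rt_set("a", "percussion", 500.0),
                           constant_rt_set("b", "brass", 500.0)],
                          ignore_index=True)
        table = rt_medians(ParticipantSet.from_frame(frame))
        diffs = group_rt_differences(table)
        assert (diffs[["median", "minimum", "maximum"]] == 0).all().all()

    def test_constant_shift(self):
        frame = pd.concat([constant_rt_set("a", "percussion", 426.0),
                           constant_rt_set("b", "brass", 500.0)],
                          ignore_index=True)
        diffs = group_rt_differences(
            rt_medians(ParticipantSet.from_frame(frame)))
        row = diffs[diffs["pair"] == "percussion-brass"].iloc[0]
        assert row["median"] == row["minimum"] == row["maximum"] == -74.0
        assert row["n_conditions"] == 28

    def test_generator_offsets_recovered(self):
        spec = CohortSpec(group_sizes={"percussion": 15, "brass": 15,
                                       "color_guard": 15}, seed=41)
        diffs = group_rt_differences(
            rt_medians(simulate_cohort(spec, trial_seed=42)))
        med = diffs.set_index("pair")["median"]
        assert med["percussion-brass"] == pytest.approx(-74, abs=20)
        assert med["brass-color_guard"] == pytest.approx(-66, abs=20)
        assert med["percussion-color_guard"] == pytest.approx(-138, abs=25)

    def test_missing_group_rejected(self):
        table = rt_medians(ParticipantSet.from_frame(
            constant_rt_set("a", "brass", 500.0)))
        with pytest.raises(ParameterError):
            group_rt_differences(table)


class TestOrderingProbability:
    @pytest.mark.parametrize("conditions, groups, expected", [
        (1, 3, 1 / 6), (2, 2, 0.25), (1, 2, 0.5),
    ])
    def test_hand_arithmetic(self, conditions, groups, expected):
        assert ordering_probability(conditions, groups) == pytest.approx(expected)

    def test_study_sized_bound(self):
        p = ordering_probability(28, 3)
        assert p == pytest.approx(1.6284e-22, rel=1e-3)
        assert p <= 1.63e-22

    def test_preconditions(self):
        with pytest.raises(ParameterError):
            ordering_probability(0, 3)
        with pytest.raises(ParameterError):
            ordering_probability(5, 1)


class TestRankCorrelations:
    def test_perfect_concordance(self):
        rc = rank_correlations([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rc.r == pytest.approx(1.0)

    def test_perfect_discordance(self):
        rc = rank_correlations([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert rc.r == pytest.approx(-1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_invariance_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=20), rng.normal(size=20)
        base = rank_correlations(a, b).r
        assert rank_correlations(np.exp(a), b ** 3).r == pytest.approx(
            base, abs=1e-12)

    def test_bivariate_normal_rho_08(self):
        rng = np.random.default_rng(77)
        x = rng.standard_normal(500)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(500)
        rc = rank_correlations(x, y)
        # Spearman's rho for bivariate normal: (6/pi) asin(rho/2) = 0.786
        assert rc.r == pytest.approx(0.786, abs=0.04)

    def test_constant_metric_rejected(self):
        with pytest.raises(DegenerateInputError):
            rank_correlations([1.0] * 6, [1, 2, 3, 4, 5, 6])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ParameterError):
            rank_correlations([1, 2, 3], [3, 2, 1])


class TestConditionMatrices:
    def test_six_pairs_per_group(self, tiny_cohort):
        wide = rt_condition_medians(tiny_cohort)
        mat = condition_rank_matrix(wide)
        assert set(mat["group"]) == {"percussion", "brass", "color_guard"}
        assert (mat.groupby("group").size() == 6).all()
        assert mat["r"].between(-1, 1).all()

    def test_consistent_individual_differences_in_dprime(self):
        """The shared observer factor yields positive cross-condition d'
        rank correlations, the within-group consistency pattern."""
        spec = CohortSpec(group_sizes={"brass": 20}, seed=51)
        ps = simulate_cohort(spec, trial_seed=52)
        dp = dprime_frame(ps)
        pooled = dp[dp["asynchrony_class"] == "pooled"].copy()
        pooled["condition"] = (pooled["motion_type"] + "_"
                               + pooled["initial_directions"])
        wide = pooled.pivot_table(index=["participant_id", "group"],
                                  columns="condition", values="dprime",
                                  aggfunc="first").reset_index()
        wide.columns.name = None
        mat = condition_rank_matrix(wide)
        assert (mat["r"] > 0).all()

    def test_rt_dprime_ranks_couple_through_group_structure(self, tiny_cohort):
        """Groups that respond faster also discriminate better, so jointly
        ranked RT and d' correlate positively across the cohort."""
        dp = dprime_frame(tiny_cohort)
        pooled = dp[dp["asynchrony_class"] == "pooled"].copy()
        pooled["condition"] = (pooled["motion_type"] + "_"
                               + pooled["initial_directions"])
        dp_wide = pooled.pivot_table(index=["participant_id", "group"],
                                     columns="condition", values="dprime",
                                     aggfunc="first").reset_index()
        dp_wide.columns.name = None
        table = rt_dprime_rank_table(rt_condition_medians(tiny_cohort), dp_wide)
        assert len(table) == 4
        assert (table["r"] > 0).all()
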