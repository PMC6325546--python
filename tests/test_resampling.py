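"""Permutation inference: hand-checked statistics, exhaustive-enumeration
oracles, within-participant shuffle invariants, and Lilliefors screening."""

from itertools import combinations, permutations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

from tojlab.errors import (DegenerateInputError, ParameterError,
                           ValidationError)
from tojlab.resampling import (_permute_within_rows, group_median_diff,
                               interaction_stat, lilliefors, permute_groups,
                               permute_interaction)


def exact_pairwise_p(d1, d2, observed):
    """Enumerate every group-size-preserving partition of the pooled values."""
    pooled = np.array(list(d1) + list(d2), dtype=float)
    n, n1 = len(pooled), len(d1)
    stats = []
    for idx in combinations(range(n), n1):
        rest = [i for i in range(n) if i not in idx]
        stats.append(np.median(pooled[list(idx)]) - np.median(pooled[rest]))
    return float(np.mean(np.asarray(stats) >= observed))


def exact_interaction_p(values, observed):
    """Enumerate all 24^n within-participant label assignments."""
    values = np.asarray(values, dtype=float)
    perms = list(permutations(range(4)))
    stats = []
    for combo in product(perms, repeat=values.shape[0]):
        arr = np.stack([row[list(p)] for row, p in zip(values, combo)])
        med = np.median(arr, axis=0)
        stats.append((med[0] - med[1]) - (med[2] - med[3]))
    return float(np.mean(np.asarray(stats) >= observed))


class TestGroupMedianDiff:
    def test_hand_computed(self):
        assert group_median_diff([1.0, 1.2, 1.4], [0.4, 0.6, 0.8]) == \
            pytest.approx(0.6)

    def test_identical_groups(self):
        assert group_median_diff([1, 2, 3], [1, 2, 3]) == 0.0

    def test_even_groups_use_midpoint(self):
        assert group_median_diff([1.0, 2.0], [0.0]) == pytest.approx(1.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=8),
           st.lists(st.floats(-5, 5), min_size=1, max_size=8))
    def test_antisymmetry(self, a, b):
        assert group_median_diff(a, b) == pytest.approx(
            -group_median_diff(b, a), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            group_median_diff([], [1.0])


class TestPermuteGroups:
    def test_seed_determines_everything(self):
        a, b = [0.2, 0.9, 1.4, 0.1], [0.5, 0.3, 0.8]
        r1 = permute_groups(a, b, n_sims=2000, seed=5)
        r2 = permute_groups(a, b, n_sims=2000, seed=5)
        assert np.array_equal(r1.null_stats, r2.null_stats)
        assert r1.p_value == r2.p_value and r1.significant == r2.significant

    def test_complete_separation_small_p(self):
        """Fully separated groups of distinct values attain a near-minimal
        rank proportion (2 of the 20 partitions reach the observed
        difference)."""
        d1, d2 = [3.0, 4.0, 5.0], [0.0, 1.0, 2.0]
        res = permute_groups(d1, d2, n_sims=5000, seed=1)
        assert exact_pairwise_p(d1, d2, res.observed_stat) == pytest.approx(0.1)
        assert res.p_value == pytest.approx(0.1, abs=0.02)

    def test_tied_values_keep_median_null_honest(self):
        """With {2,2,2} vs {0,0,0} half the partitions reproduce the
        observed median difference, so the exact p is 0.5 — separation in
        values does not imply a small p for a median statistic."""
        d1, d2 = [2.0, 2.0, 2.0], [0.0, 0.0, 0.0]
        res = permute_groups(d1, d2, n_sims=5000, seed=1)
        assert exact_pairwise_p(d1, d2, res.observed_stat) == pytest.approx(0.5)
        assert res.p_value == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("n1, n2, seed", [(3, 3, 0), (4, 4, 1), (5, 3, 2)])
    def test_exhaustive_enumeration_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        d1, d2 = rng.normal(0.4, 1.0, n1), rng.normal(0.0, 1.0, n2)
        res = permute_groups(d1, d2, n_sims=10_000, seed=seed + 100)
        p_exact = exact_pairwise_p(d1, d2, res.observed_stat)
        tol = max(3 * np.sqrt(p_exact * (1 - p_exact) / res.n_sims), 3e-4)
        assert abs(res.p_value - p_exact) <= tol

    def test_plus_one_convention(self):
        res = permute_groups([1.0, 2.0], [0.0, 0.5], n_sims=100, seed=0,
                             plus_one=True)
        count = int(np.sum(res.null_stats >= res.observed_stat))
        assert res.p_value == pytest.approx((count + 1) / 101)

    def test_invalid_n_sims(self):
        with pytest.raises(ParameterError):
            permute_groups([1.0], [2.0], n_sims=0)


class TestInteraction:
    def test_null_interaction(self):
        vals = np.tile([1.0, 1.0, 1.0, 1.0], (5, 1))
        assert interaction_stat(vals) == 0.0

    def test_hand_arithmetic(self):
        # medians (RS, RO, RotS, RotO) = (1.0, 0.5, 0.8, 0.9) -> 0.6
        vals = np.array([[1.0, 0.5, 0.8, 0.9]] * 3)
        assert interaction_stat(vals) == pytest.approx(0.6)

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(6, 4))
        swapped = vals[:, [2, 3, 0, 1]]      # radial <-> rotational
        assert interaction_stat(swapped) == pytest.approx(
            -interaction_stat(vals), abs=1e-12)

    def test_missing_cell_rejected(self):
        vals = np.array([[1.0, 0.5, np.nan, 0.9]])
        with pytest.raises(ValidationError):
            interaction_stat(vals)

    def test_within_participant_shuffle_preserves_multisets(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(9, 4))
        perm = _permute_within_rows(vals, 200, np.random.default_rng(4))
        assert np.allclose(np.sort(perm, axis=2),
                           np.sort(vals, axis=1)[None, :, :])

    def test_exhaustive_enumeration_oracle_three_participants(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, size=(3, 4)) + [0.8, 0.0, 0.2, 0.1]
        res = permute_interaction(vals, n_sims=10_000, seed=7)
        p_exact = exact_interaction_p(vals, res.observed_stat)
        tol = max(3 * np.sqrt(p_exact * (1 - p_exact) / res.n_sims), 3e-4)
        assert abs(res.p_value - p_exact) <= tol

    def test_power_on_injected_interaction(self):
        """Delta = 1.0 d' at n = 25, sd = 0.4: detected at p < 0.01 in at
        least 95% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            base = rng.normal(1.5, 0.4, size=(25, 1))
            vals = base + rng.normal(0, 0.4, size=(25, 4))
            vals[:, 0] += 0.5   # RS up, RO down: contrast = 1.0
            vals[:, 1] -= 0.5
            res = permute_interaction(vals, n_sims=1500, seed=seed)
            hits += res.p_value < 0.01
        assert hits >= int(np.ceil(0.95 * n_seeds))


class TestLilliefors:
    def test_small_sample_rejected(self):
        with pytest.raises(ParameterError):
            lilliefors([1.0, 2.0, 3.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            lilliefors([2.0] * 10)

    def test_statistic_matches_reference_implementation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=80)
        stat, p = lilliefors(x, seed=9)
        ref_stat, ref_p = sm_lilliefors(x, dist="norm")
        assert stat == pytest.approx(ref_stat, abs=1e-12)
        assert p == pytest.approx(ref_p, abs=0.05)

    def test_calibration_on_normal_samples(self):
        keep = 0
        n_seeds = 50
        for seed in range(n_seeds):
            x = np.random.default_rng(2000 + seed).standard_normal(100)
            _, p = lilliefors(x, n_reps=2000, seed=seed)
            keep += p > 0.05
        assert keep >= int(np.ceil(0.94 * n_seeds))

    def test_power_against_exponential(self):
        rejections = 0
        n_seeds = 30
        for seed in range(n_seeds):
            x = np.random.default_rng(3000 + seed).exponential(size=100)
            _, p = lilliefors(x, n_reps=2000, seed=seed)
            rejections += p < 0.05
        assert rejections >= int(np.ceil(0.99 * n_seeds))
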