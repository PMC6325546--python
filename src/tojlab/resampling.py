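"""Median-based Monte Carlo permutation inference and normality screening.

Two permutation procedures, both on medians because several conditions fail
normality (screened here by a Lilliefors test):

* pairwise group differences — the observed statistic is the difference of
  group medians in d'; each of the (default 10,000) simulations randomly
  re-partitions the pooled values into the original group sizes and
  recomputes the statistic. Significance is declared when the observed
  difference exceeds the 95th percentile of the simulated null (one-sided
  by default).

* 2x2 motion-type x initial-directions interaction — the observed statistic
  is (median RS - median RO) - (median RotS - median RotO) over the group's
  per-participant cell values; each simulation independently permutes,
  within every participant, that participant's four cell values across the
  four condition labels, exactly preserving consistent individual
  differences.

p-values are rank proportions, count(null >= observed)/n_sims, without the
+1 correction by default (a ``plus_one`` flag adds it). Results are fully
determined by (seed, n_sims).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import DegenerateInputError, ParameterError, ValidationError
#: canonical column order of the four cells in an interaction matrix
CELL_ORDER = ("radial_same", "radial_opposite",
              "rotational_same", "rotational_opposite")

DEFAULT_N_SIMS = 10_000
LILLIEFORS_DEFAULT_REPS = 10_000


@dataclass
class PermutationResult:
    """Observed statistic, simulated null, and rank-based p-value."""

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_sims: int
    seed: int
    direction: str                 # "greater" | "two_sided"
    significant: bool              # observed beyond the 95th null percentile
    plus_one: bool = False

    def __post_init__(self):
        self.null_stats = np.asarray(self.null_stats, dtype=float)
        if len(self.null_stats) != self.n_sims:
            raise ParameterError("null_stats length must equal n_sims")
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError("p_value outside [0, 1]")


def group_median_diff(d1: Sequence[float], d2: Sequence[float]) -> float:
    """median(d1) - median(d2); even groups use the midpoint median."""
    a = np.asarray(list(d1), dtype=float)
    b = np.asarray(list(d2), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    return float(np.median(a) - np.median(b))


def _p_and_flag(observed: float, null: np.ndarray, direction: str,
                plus_one: bool):
    if direction == "greater":
        count = int(np.sum(null >= observed))
        significant = observed > np.percentile(null, 95)
    elif direction == "two_sided":
        count = int(np.sum(np.abs(null) >= abs(observed)))
        significant = abs(observed) > np.percentile(np.abs(null), 95)
    else:
        raise ParameterError(f"unknown direction {direction!r}")
    n = len(null)
    p = (count + 1) / (n + 1) if plus_one else count / n
    return float(p), bool(significant)


def permute_groups(d1: Sequence[float], d2: Sequence[float],
                   n_sims: int = DEFAULT_N_SIMS, seed: int = 0,
                   direction: str = "greater",
                   plus_one: bool = False) -> PermutationResult:
    """Monte Carlo permutation test of a median group difference.

    Each simulation shuffles the pooled values and splits them back into
    groups of the original sizes (group-size-preserving partition drawn by
    permuting the pooled index vector).
    """
    if n_sims < 1:
        raise ParameterError("n_sims must be >= 1")
    a = np.asarray(list(d1), dtype=float)
    b = np.asarray(list(d2), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if pooled.size < 2:
        raise ParameterError("need at least two values in total")
    observed = group_median_diff(a, b)
    rng = np.random.default_rng(seed)
    n1 = a.size
    # vectorized random partitions: argsort of uniforms = random permutation
    order = np.argsort(rng.random((n_sims, pooled.size)), axis=1)
    perm = pooled[order]
    null = np.median(perm[:, :n1], axis=1) - np.median(perm[:, n1:], axis=1)
    p, sig = _p_and_flag(observed, null, direction, plus_one)
    return PermutationResult(observed_stat=observed, null_stats=null,
                             p_value=p, n_sims=n_sims, seed=seed,
                             direction=direction, significant=sig,
                             plus_one=plus_one)


def _as_cell_matrix(cond_values) -> np.ndarray:
    """Coerce per-participant cell values to an (n, 4) array in CELL_ORDER."""
    if isinstance(cond_values, pd.DataFrame):
        missing = [c for c in CELL_ORDER if c not in cond_values.columns]
        if missing:
            raise ValidationError(f"missing cell columns {missing}")
        arr = cond_values[list(CELL_ORDER)].to_numpy(dtype=float)
    else:
        arr = np.asarray(cond_values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValidationError("expected an (n_participants, 4) cell matrix")
    if arr.shape[0] < 1:
        raise ValidationError("need at least one participant")
    if not np.isfinite(arr).all():
        raise ValidationError("missing (non-finite) cell values")
    return arr


def interaction_stat(cond_values) -> float:
    """2x2 contrast on the group medians of the four cells:
    (med RS - med RO) - (med RotS - med RotO)."""
    arr = _as_cell_matrix(cond_values)
    m = np.median(arr, axis=0)
    return float((m[0] - m[1]) - (m[2] - m[3]))


def _permute_within_rows(arr: np.ndarray, n_sims: int,
                         rng: np.random.Generator) -> np.ndarray:
    """(n_sims, n, 4) array: each participant's 4 values independently
    permuted across the condition labels in every simulation."""
    n = arr.shape[0]
    idx = np.argsort(rng.random((n_sims, n, 4)), axis=2)
    return np.take_along_axis(np.broadcast_to(arr, (n_sims, n, 4)), idx, axis=2)


def permute_interaction(cond_values, n_sims: int = DEFAULT_N_SIMS,
                        seed: int = 0, direction: str = "greater",
                        plus_one: bool = False) -> PermutationResult:
    """Within-participant permutation test of the 2x2 interaction.

    Every simulation permutes each participant's four cell values across
    the four condition labels, leaving each participant's multiset of
    values — their overall level — untouched.
    """
    if n_sims < 1:
        raise ParameterError("n_sims must be >= 1")
    arr = _as_cell_matrix(cond_values)
    observed = interaction_stat(arr)
    rng = np.random.default_rng(seed)
    perm = _permute_within_rows(arr, n_sims, rng)
    med = np.median(perm, axis=1)                      # (n_sims, 4)
    null = (med[:, 0] - med[:, 1]) - (med[:, 2] - med[:, 3])
    p, sig = _p_and_flag(observed, null, direction, plus_one)
    return PermutationResult(observed_stat=observed, null_stats=null,
                             p_value=p, n_sims=n_sims, seed=seed,
                             direction=direction, significant=sig,
                             plus_one=plus_one)


def _ks_distance_to_fitted_normal(values: np.ndarray) -> float:
    """KS distance between the sample ECDF and a normal with the sample's
    mean and SD (ddof=1)."""
    n = values.shape[-1]
    mean = values.mean(axis=-1, keepdims=True)
    sd = values.std(axis=-1, ddof=1, keepdims=True)
    z = np.sort((values - mean) / sd, axis=-1)
    cdf = ndtr(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=-1)
    d_minus = (cdf - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def lilliefors(values: Sequence[float],
               n_reps: int = LILLIEFORS_DEFAULT_REPS,
               seed: int = 0) -> tuple[float, float]:
    """Lilliefors normality test: KS distance to a normal with estimated
    mean/SD, with the p-value from ``n_reps`` Monte Carlo replicates of
    standard-normal samples of the same size (seeded, hence reproducible).

    Returns ``(statistic, p_value)``; requires n >= 4 and a non-constant
    sample.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise ParameterError("Lilliefors test requires n >= 4")
    if np.ptp(arr) == 0:
        raise DegenerateInputError("constant sample: normality is undefined")
    stat = float(_ks_distance_to_fitted_normal(arr[None, :])[0])
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_reps, arr.size))
    null = _ks_distance_to_fitted_normal(sims)
    p = float(np.mean(null >= stat))
    return stat, p
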