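"""Synthetic TOJ observers with the statistical structure the analysis assumes.

Each observer responds "left first" with probability

    P(left_first | X) = lambda/2 + (1 - lambda) / (1 + exp(-K (X - Xo)))

per stimulus cell (motion type x initial directions): a 2-parameter logistic
in the signed asynchrony X with slope ``K`` (1/ms) and midpoint ``Xo`` (ms),
floored/ceiled symmetrically by a lapse rate ``lambda`` so the generative
midpoint stays at Xo. The observer's 75% threshold in a cell is ln(3)/K.

Reaction times are drawn from a shifted lognormal (positive support, right
skew) whose median is ``rt_base_ms``, with an additive central-tendency
penalty at the zero asynchrony where the stimulus carries no order
information.

A cohort mirrors the study's structure: percussion/brass/color-guard groups
whose median thresholds differ by group, modulated per cell by an
interaction profile that makes radial-opposite hardest and
rotational-opposite relatively easy. Guessers (observers at chance) can be
appended per group to exercise the inclusion screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .trial_model import (ANALYSIS_BLOCKS, CONDITIONS, GROUPS,
                          NOMINAL_ASYNCHRONIES_MS, TRIALS_PER_CELL,
                          ParticipantSet)

LN3 = math.log(3.0)

Cell = Tuple[str, str]

#: Threshold assigned to guessing observers; flat response curve over the
#: +/-200 ms stimulus range.
GUESSER_THRESHOLD_MS = 1e9


@dataclass(frozen=True)
class ObserverSpec:
    """Generative parameters of one synthetic participant."""

    participant_id: str
    group: str
    k_cell: Mapping[Cell, float]          # logistic slope per cell, 1/ms
    xo_cell: Mapping[Cell, float]         # midpoint (bias) per cell, ms
    lapse: float = 0.0                    # proportion in [0, 0.1]
    rt_base_ms: float = 650.0             # median RT
    rt_zero_penalty_ms: float = 150.0     # added slowing at X = 0
    rt_noise_scale: float = 0.25          # lognormal sigma of RT noise

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ParameterError(f"unknown group {self.group!r}")
        for cell in CONDITIONS:
            if cell not in self.k_cell or cell not in self.xo_cell:
                raise ParameterError(f"observer missing cell {cell}")
            if not self.k_cell[cell] > 0:
                raise ParameterError(f"K must be > 0 in cell {cell}")
        if not (0.0 <= self.lapse <= 0.1):
            raise ParameterError("lapse must lie in [0, 0.1]")
        if not self.rt_base_ms > 0:
            raise ParameterError("rt_base_ms must be > 0")
        if self.rt_zero_penalty_ms < 0:
            raise ParameterError("rt_zero_penalty_ms must be >= 0")

    def threshold_ms(self, cell: Cell) -> float:
        """75% threshold ln(3)/K of this observer in ``cell``."""
        return LN3 / self.k_cell[cell]


def _default_group_sizes() -> Dict[str, int]:
    return {"percussion": 25, "brass": 67, "color_guard": 29}


def _default_thresholds() -> Dict[str, float]:
    return {"percussion": 40.0, "brass": 80.0, "color_guard": 160.0}


def _default_profile() -> Dict[Cell, float]:
    # multiplicative threshold modifier: radial-opposite hardest,
    # rotational-opposite relatively easy
    return {("radial", "same"): 1.0, ("radial", "opposite"): 2.0,
            ("rotational", "same"): 1.0, ("rotational", "opposite"): 0.8}


def _default_rt_base() -> Dict[str, float]:
    return {"percussion": 600.0, "brass": 674.0, "color_guard": 740.0}


def _default_guessers() -> Dict[str, int]:
    return {"percussion": 0, "brass": 0, "color_guard": 0}


@dataclass
class CohortSpec:
    """Group-level generative distributions for a synthetic cohort.

    Defaults emulate the study conditions: 25/67/29 above-chance observers,
    group median thresholds spanning roughly an order of magnitude, an
    interaction profile over the 2x2 stimulus cells, and group RT offsets of
    about -74 (percussion vs brass) and -66 ms (brass vs color guard).
    """

    group_sizes: Dict[str, int] = field(default_factory=_default_group_sizes)
    median_threshold_ms: Dict[str, float] = field(default_factory=_default_thresholds)
    threshold_dispersion: float = 0.3      # lognormal sigma, observer level
    interaction_profile: Dict[Cell, float] = field(default_factory=_default_profile)
    bias_sd_ms: float = 8.0
    lapse_max: float = 0.04
    rt_base_ms: Dict[str, float] = field(default_factory=_default_rt_base)
    rt_dispersion: float = 0.08            # lognormal sigma across observers
    rt_zero_penalty_ms: float = 150.0
    rt_noise_scale: float = 0.25
    n_guessers: Dict[str, int] = field(default_factory=_default_guessers)
    seed: int = 0

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ParameterError(f"unknown group {g!r}")
            if n < 1:
                raise ParameterError(f"group size for {g} must be >= 1")
        for name, val in (("threshold_dispersion", self.threshold_dispersion),
                          ("rt_dispersion", self.rt_dispersion),
                          ("bias_sd_ms", self.bias_sd_ms)):
            if val < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0.0 <= self.lapse_max <= 0.1):
            raise ParameterError("lapse_max must lie in [0, 0.1]")
        for cell in CONDITIONS:
            if self.interaction_profile.get(cell, 0) <= 0:
                raise ParameterError(f"interaction profile must be > 0 for {cell}")


def sample_cohort(spec: CohortSpec) -> list[ObserverSpec]:
    """Draw one observer per cohort slot; reproducible given ``spec.seed``.

    Observer thresholds are ``target(group) * profile(cell) * exp(s Z_i)
    * exp(s/2 Z_ic)`` with ``s = threshold_dispersion``: a shared lognormal
    observer factor (consistent individual differences across cells) plus a
    half-strength per-cell jitter. With zero dispersion every observer sits
    exactly at the group target.
    """
    rng = np.random.default_rng(spec.seed)
    observers: list[ObserverSpec] = []
    cell_sigma = spec.threshold_dispersion / 2.0
    for group in GROUPS:
        if group not in spec.group_sizes:
            continue
        n = spec.group_sizes[group]
        n_guess = spec.n_guessers.get(group, 0)
        target = spec.median_threshold_ms[group]
        for i in range(n + n_guess):
            pid = f"{group}-{i + 1:03d}"
            is_guesser = i >= n
            z_obs = rng.standard_normal()
            k_cell, xo_cell = {}, {}
            for cell in CONDITIONS:
                z_c = rng.standard_normal()
                if is_guesser:
                    thr = GUESSER_THRESHOLD_MS
                else:
                    thr = (target * spec.interaction_profile[cell]
                           * math.exp(spec.threshold_dispersion * z_obs)
                           * math.exp(cell_sigma * z_c))
                k_cell[cell] = LN3 / thr
                xo_cell[cell] = rng.normal(0.0, spec.bias_sd_ms) if spec.bias_sd_ms else 0.0
            lapse = rng.uniform(0.0, spec.lapse_max) if spec.lapse_max else 0.0
            rt_base = spec.rt_base_ms[group] * math.exp(
                spec.rt_dispersion * rng.standard_normal())
            observers.append(ObserverSpec(
                participant_id=pid, group=group, k_cell=k_cell,
                xo_cell=xo_cell, lapse=lapse, rt_base_ms=rt_base,
                rt_zero_penalty_ms=spec.rt_zero_penalty_ms,
                rt_noise_scale=spec.rt_noise_scale))
    return observers


def response_probability(k: float, xo: float, lapse: float, x) -> np.ndarray:
    """Closed-form P(left_first | X) of the lapse-floored logistic."""
    x = np.asarray(x, dtype=float)
    return lapse / 2.0 + (1.0 - lapse) / (1.0 + np.exp(-k * (x - xo)))


def simulate_trials(observers: Sequence[ObserverSpec], seed: int,
                    reps_per_cell: int = TRIALS_PER_CELL,
                    asynchronies: Sequence[float] = NOMINAL_ASYNCHRONIES_MS,
                    include_practice: bool = False,
                    provenance: Mapping | None = None) -> ParticipantSet:
    """Simulate the full trial table for ``observers``.

    The default design is the study's 2 x 2 x 7 x 20 layout in five analysis
    blocks (block = 1..5, four repeats of each cell per block), optionally
    preceded by a practice block 0 of four repeats per cell. Overriding
    ``reps_per_cell`` or ``asynchronies`` produces a deliberately
    non-canonical design and skips the cell-count validation.
    """
    if len(observers) == 0:
        raise ParameterError("need at least one observer")
    if reps_per_cell < 1:
        raise ParameterError("reps_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    default_design = (reps_per_cell == TRIALS_PER_CELL
                      and tuple(asynchronies) == tuple(NOMINAL_ASYNCHRONIES_MS))

    asyn = np.asarray(list(asynchronies), dtype=float)
    n_cells = len(CONDITIONS) * len(asyn)

    # per-cell design arrays, repeated reps_per_cell times
    motion = np.repeat([m for m, _ in CONDITIONS], len(asyn))
    dirs = np.repeat([d for _, d in CONDITIONS], len(asyn))
    xs = np.tile(asyn, len(CONDITIONS))

    blocks_spec = []
    if include_practice:
        blocks_spec.append((0, max(1, reps_per_cell // ANALYSIS_BLOCKS)))
    rep_block = 1 + (np.arange(reps_per_cell) * ANALYSIS_BLOCKS) // reps_per_cell
    frames = []
    for obs in observers:
        k = np.array([obs.k_cell[(m, d)] for m, d in zip(motion, dirs)])
        xo = np.array([obs.xo_cell[(m, d)] for m, d in zip(motion, dirs)])

        blk_ids = [b for b, n in blocks_spec for _ in range(n)] + list(rep_block)
        total_reps = len(blk_ids)

        row_x = np.tile(xs, total_reps)
        row_k = np.tile(k, total_reps)
        row_xo = np.tile(xo, total_reps)
        row_motion = np.tile(motion, total_reps)
        row_dirs = np.tile(dirs, total_reps)
        row_block = np.repeat(blk_ids, n_cells)
        n_rows = len(row_x)

        p_left = obs.lapse / 2.0 + (1.0 - obs.lapse) / (
            1.0 + np.exp(-row_k * (row_x - row_xo)))
        left = rng.random(n_rows) < p_left
        response = np.where(left, "left_first", "right_first")

        # correctness: sign rule off zero; pre-designated fair coin at zero
        zero = row_x == 0
        predesignated_left = rng.random(n_rows) < 0.5
        correct = np.where(
            zero, left == predesignated_left, left == (row_x > 0))

        # shifted lognormal RT with median rt_base, plus zero-asynchrony penalty
        z = rng.standard_normal(n_rows)
        rt = (0.5 * obs.rt_base_ms
              + 0.5 * obs.rt_base_ms * np.exp(obs.rt_noise_scale * z))
        # millisecond timestamps carry microsecond precision at most;
        # rounding here also makes CSV round-trips exactly lossless
        rt = np.round(rt + np.where(zero, obs.rt_zero_penalty_ms, 0.0), 3)

        frames.append(pd.DataFrame({
            "participant_id": obs.participant_id,
            "group": obs.group,
            "motion_type": row_motion,
            "initial_directions": row_dirs,
            "asynchrony_ms": row_x,
            "response": response,
            "designated_correct": correct,
            "rt_ms": rt,
            "block": row_block,
        }))

    trials = pd.concat(frames, ignore_index=True)
    prov = dict(provenance or {})
    prov.setdefault("generator", "tojlab.synthetic_data")
    prov["trial_seed"] = int(seed)
    return ParticipantSet.from_frame(trials, provenance=prov,
                                     validate_design=default_design)


def simulate_cohort(spec: CohortSpec, trial_seed: int | None = None,
                    include_practice: bool = False) -> ParticipantSet:
    """Sample a cohort from ``spec`` and simulate its trials.

    Cohort sampling is governed by ``spec.seed``, trial simulation by
    ``trial_seed`` (default ``spec.seed + 1``); both are recorded in the
    provenance of the returned set.
    """
    if trial_seed is None:
        trial_seed = spec.seed + 1
    observers = sample_cohort(spec)
    return simulate_trials(
        observers, seed=trial_seed, include_practice=include_practice,
        provenance={"cohort_seed": int(spec.seed), "trial_seed": int(trial_seed)})


def cohort_spec_from_dict(d: Mapping) -> CohortSpec:
    """Build a :class:`CohortSpec` from a plain (YAML/JSON) mapping.

    Condition-keyed fields use ``"motion:directions"`` string keys, e.g.
    ``{"radial:opposite": 2.0}``.
    """
    kwargs = dict(d)
    if "interaction_profile" in kwargs:
        prof = {}
        for key, val in kwargs["interaction_profile"].items():
            m, sep, dd = str(key).partition(":")
            if not sep:
                raise ParameterError(
                    f"interaction_profile key {key!r} must be 'motion:directions'")
            prof[(m, dd)] = float(val)
        kwargs["interaction_profile"] = prof
    return CohortSpec(**kwargs)
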