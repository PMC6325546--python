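"""Shared fixtures: deterministic hand-built participants and small
synthetic cohorts."""

from __future__ import annotations

import pandas as pd
import pytest

from tojlab.synthetic_data import CohortSpec, simulate_cohort
from tojlab.trial_model import (CONDITIONS, NOMINAL_ASYNCHRONIES_MS,
                                TRIALS_PER_CELL, ParticipantSet)


def build_trials(pid, group, chooser, rt=500.0, rt_fn=None) -> pd.DataFrame:
    """Deterministic 560-trial frame for one participant.

    ``chooser(motion, dirs, x, rep) -> bool`` decides left-first;
    correctness follows the sign rule off zero and alternates the
    pre-designated answer at zero. ``rt_fn`` optionally varies RT per trial.
    """
    rows = []
    for m, d in CONDITIONS:
        for x in NOMINAL_ASYNCHRONIES_MS:
            for rep in range(TRIALS_PER_CELL):
                left = bool(chooser(m, d, x, rep))
                if x == 0:
                    predesignated_left = rep % 2 == 0
                    correct = left == predesignated_left
                else:
                    correct = left == (x > 0)
                rows.append({
                    "participant_id": pid, "group": group,
                    "motion_type": m, "initial_directions": d,
                    "asynchrony_ms": x,
                    "response": "left_first" if left else "right_first",
                    "designated_correct": correct,
                    "rt_ms": float(rt_fn(m, d, x, rep)) if rt_fn else float(rt),
                    "block": 1 + rep // 4,
                })
    return pd.DataFrame(rows)


def perfect_chooser(m, d, x, rep):
    """Always correct off zero; alternating at zero."""
    return x > 0 if x != 0 else rep % 2 == 0


@pytest.fixture(scope="session")
def perfect_set() -> ParticipantSet:
    frame = build_trials("p01", "percussion", perfect_chooser)
    return ParticipantSet.from_frame(frame)


@pytest.fixture(scope="session")
def tiny_cohort() -> ParticipantSet:
    """4 observers per group, moderate dispersion; 12 x 560 trials."""
    spec = CohortSpec(
        group_sizes={"percussion": 4, "brass": 4, "color_guard": 4},
        threshold_dispersion=0.2, seed=11)
    return simulate_cohort(spec, trial_seed=12)
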