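"""Participant screening: exact binomial test against chance.

A participant enters the analyses only if their TOJ accuracy over the 480
nonzero-asynchrony analysis trials statistically exceeds chance by an exact
one-tailed binomial test at p < 0.001 (strict). Zero-asynchrony trials
carry no objectively correct answer and never count. The smallest count
meeting the criterion, expressed as a percentage, is the operational
minimum percent correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import binom

from .errors import ValidationError
from .trial_model import (GROUPS, NONZERO_TRIALS_PER_PARTICIPANT,
                          ParticipantSet)

ALPHA = 0.001


def binomial_exceeds_chance_p(n_correct: int, n_trials: int) -> float:
    """Exact upper-tail P(X >= n_correct) for X ~ Binomial(n_trials, 0.5)."""
    return float(binom.sf(n_correct - 1, n_trials, 0.5))


def minimal_included_count(n_trials: int = NONZERO_TRIALS_PER_PARTICIPANT,
                           alpha: float = ALPHA) -> tuple[int, float]:
    """Smallest correct count k* with exact tail p < alpha, and k*/n as %."""
    k = int(binom.isf(alpha, n_trials, 0.5))
    # isf gives a neighborhood; walk to the exact strict-inequality boundary
    while binomial_exceeds_chance_p(k, n_trials) >= alpha:
        k += 1
    while k > 0 and binomial_exceeds_chance_p(k - 1, n_trials) < alpha:
        k -= 1
    return k, 100.0 * k / n_trials


@dataclass
class InclusionReport:
    """Per-participant screening rows plus per-group inclusion summary."""

    participants: pd.DataFrame   # pid, group, n_correct, percent_correct, p_value, included
    groups: pd.DataFrame         # group, n_total, n_included, percent_included

    @property
    def included_ids(self) -> list[str]:
        inc = self.participants[self.participants["included"]]
        return inc["participant_id"].tolist()


def screen_participant(trials_one: pd.DataFrame,
                       n_trials: int = NONZERO_TRIALS_PER_PARTICIPANT) -> dict:
    """Screening row for one participant's trials (analysis blocks).

    Requires exactly ``n_trials`` nonzero-asynchrony analysis trials.
    """
    analysis = trials_one[trials_one["block"] > 0]
    nz = analysis[analysis["asynchrony_ms"] != 0]
    if len(nz) != n_trials:
        pid = trials_one["participant_id"].iloc[0] if len(trials_one) else "?"
        raise ValidationError(
            f"participant {pid!r} has {len(nz)} nonzero-asynchrony analysis "
            f"trials; expected {n_trials}")
    n_correct = int(nz["designated_correct"].sum())
    p = binomial_exceeds_chance_p(n_correct, n_trials)
    return {
        "participant_id": str(nz["participant_id"].iloc[0]),
        "group": nz["group"].iloc[0],
        "n_correct": n_correct,
        "percent_correct": 100.0 * n_correct / n_trials,
        "p_value": p,
        "included": bool(p < ALPHA),
    }


def screen_cohort(trials: ParticipantSet) -> InclusionReport:
    """Apply the screen to every participant and summarize by group."""
    rows = [screen_participant(sub)
            for _, sub in trials.trials.groupby("participant_id", sort=True)]
    per = pd.DataFrame(rows)
    grows = []
    for group in GROUPS:
        sub = per[per["group"] == group]
        if sub.empty:
            continue
        n_total, n_inc = len(sub), int(sub["included"].sum())
        grows.append({"group": group, "n_total": n_total,
                      "n_included": n_inc,
                      "percent_included": 100.0 * n_inc / n_total})
    return InclusionReport(participants=per, groups=pd.DataFrame(grows))


def apply_screen(trials: ParticipantSet) -> tuple[ParticipantSet, InclusionReport]:
    """Screen and return (included-only ParticipantSet, report)."""
    report = screen_cohort(trials)
    return trials.subset(report.included_ids), report
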