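"""Reaction-time medians, group difference lists, and rank correlations.

The RT clock starts at the offset of the dynamic-plaid stimulus and stops
at the keypress; this convention is a constant of the data model, so all
RTs here are offset-referenced. For each participant the median RT is
computed in each of the 28 (2 motion x 2 directions x 7 asynchrony) cells;
group-level values are medians of participant medians. Group contrasts are
the 28 cell-wise differences of group medians, summarized by their median
and the smallest/largest difference by magnitude.

Rank analyses use average ranks for ties (Spearman-equivalent Pearson
correlation on ranks), computed across all included participants jointly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr, rankdata

from .errors import DegenerateInputError, ParameterError, ValidationError
from .trial_model import CONDITIONS, GROUPS, ParticipantSet

#: ordered group pairs of the difference lists (first minus second)
GROUP_PAIRS = (("percussion", "brass"), ("brass", "color_guard"),
               ("percussion", "color_guard"))


@dataclass
class RTTable:
    """Participant- and group-level median RTs in the 28 design cells."""

    participant_medians: pd.DataFrame   # long: pid, group, cell, median_rt_ms
    group_medians: pd.DataFrame         # long: group, cell, median_rt_ms


def rt_medians(trials: ParticipantSet) -> RTTable:
    """Median RT per participant per cell, then median across participants.

    Every participant must have at least one analysis trial in every cell
    they contribute to; a fully empty cell raises ValidationError.
    """
    df = trials.analysis_trials
    if df.empty:
        raise ValidationError("no analysis trials")
    cell_cols = ["motion_type", "initial_directions", "asynchrony_ms"]
    per = (df.groupby(["participant_id", "group"] + cell_cols, observed=True)
           ["rt_ms"].median().rename("median_rt_ms").reset_index())
    n_cells = per.groupby("participant_id").size()
    expected = len(CONDITIONS) * df["asynchrony_ms"].nunique()
    short = n_cells[n_cells != expected].index.tolist()
    if short:
        raise ValidationError(f"participants with empty cells: {short}")
    grp = (per.groupby(["group"] + cell_cols, observed=True)["median_rt_ms"]
           .median().reset_index())
    return RTTable(participant_medians=per, group_medians=grp)


def group_rt_differences(table: RTTable) -> pd.DataFrame:
    """Median / minimum / maximum of each ordered pair's 28 cell differences.

    Minimum and maximum are by magnitude (smallest and largest absolute
    difference), keeping the signed values.
    """
    grp = table.group_medians
    present = set(grp["group"])
    if len(present) < 2:
        raise ParameterError("need at least two groups")
    cell_cols = ["motion_type", "initial_directions", "asynchrony_ms"]
    wide = grp.pivot_table(index=cell_cols, columns="group",
                           values="median_rt_ms")
    rows = []
    for g1, g2 in GROUP_PAIRS:
        if g1 not in present or g2 not in present:
            continue
        diffs = (wide[g1] - wide[g2]).to_numpy(dtype=float)
        rows.append({
            "pair": f"{g1}-{g2}",
            "median": float(np.median(diffs)),
            "minimum": float(diffs[np.argmin(np.abs(diffs))]),
            "maximum": float(diffs[np.argmax(np.abs(diffs))]),
            "n_conditions": int(diffs.size),
        })
    return pd.DataFrame(rows)


def ordering_probability(n_conditions: int, n_groups: int) -> float:
    """Chance probability that one fixed strict group ordering recurs in
    every condition under independent uniform orderings: (1/g!)^c."""
    if n_groups < 2 or n_conditions < 1:
        raise ParameterError("need n_groups >= 2 and n_conditions >= 1")
    return (1.0 / math.factorial(n_groups)) ** n_conditions


@dataclass
class RankCorrelation:
    r: float
    p_value: float
    n: int


def rank_correlations(metric_a: Sequence[float],
                      metric_b: Sequence[float]) -> RankCorrelation:
    """Pearson correlation of average-ranked values (Spearman-equivalent)."""
    a = np.asarray(list(metric_a), dtype=float)
    b = np.asarray(list(metric_b), dtype=float)
    if a.shape != b.shape:
        raise ParameterError("metrics must be paired")
    if a.size < 4:
        raise ParameterError("rank correlation requires n >= 4")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant metric: ranks are uninformative")
    ra, rb = rankdata(a), rankdata(b)
    r, p = pearsonr(ra, rb)
    return RankCorrelation(r=float(r), p_value=float(p), n=int(a.size))


def condition_labels() -> list[str]:
    return [f"{m}_{d}" for m, d in CONDITIONS]


def condition_rank_matrix(metric_wide: pd.DataFrame) -> pd.DataFrame:
    """Within-group rank correlations between pairs of motion conditions.

    ``metric_wide`` has one row per participant with a ``group`` column and
    one column per condition label (e.g. ``radial_same``). Returns the
    condition-pair matrix in long form: group, condition_a, condition_b,
    r, p_value, n — the shape of the within-group consistency tables.
    """
    labels = [c for c in condition_labels() if c in metric_wide.columns]
    if len(labels) < 2:
        raise ParameterError("need at least two condition columns")
    rows = []
    for group in GROUPS:
        sub = metric_wide[metric_wide["group"] == group]
        if sub.empty:
            continue
        for ca, cb in combinations(labels, 2):
            rc = rank_correlations(sub[ca], sub[cb])
            rows.append({"group": group, "condition_a": ca, "condition_b": cb,
                         "r": rc.r, "p_value": rc.p_value, "n": rc.n})
    return pd.DataFrame(rows)


def rt_condition_medians(trials: ParticipantSet) -> pd.DataFrame:
    """Per participant per condition: median RT across all that condition's
    analysis trials (all seven asynchronies). Wide format with a ``group``
    column and one column per condition label."""
    df = trials.analysis_trials
    per = (df.groupby(["participant_id", "group", "motion_type",
                       "initial_directions"], observed=True)["rt_ms"]
           .median().reset_index())
    per["condition"] = per["motion_type"] + "_" + per["initial_directions"]
    wide = per.pivot_table(index=["participant_id", "group"],
                           columns="condition", values="rt_ms",
                           aggfunc="first").reset_index()
    wide.columns.name = None
    return wide


def rt_dprime_rank_table(rt_wide: pd.DataFrame,
                         dprime_wide: pd.DataFrame) -> pd.DataFrame:
    """Per condition: overall RT-rank vs d'-rank correlation (participants
    of all groups ranked jointly) plus per-group trendline slopes.

    Ranks are oriented so that better performance gets the lower rank on
    both metrics: RT ranks ascend with RT (fast = rank 1) and d' ranks
    descend with d' (most sensitive = rank 1). A positive correlation
    therefore means faster responders also discriminate better — speed and
    precision move together rather than trading off.

    Both inputs are wide per-participant frames with ``participant_id``,
    ``group`` and one column per condition label; ``dprime_wide`` holds the
    four pooled-asynchrony d' values.
    """
    merged = rt_wide.merge(dprime_wide, on=["participant_id", "group"],
                           suffixes=("_rt", "_dprime"))
    rows = []
    for cond in condition_labels():
        rt_col, dp_col = f"{cond}_rt", f"{cond}_dprime"
        if rt_col not in merged.columns or dp_col not in merged.columns:
            continue
        rc = rank_correlations(merged[rt_col], -merged[dp_col])
        row = {"condition": cond, "r": rc.r, "p_value": rc.p_value, "n": rc.n}
        rt_ranks = rankdata(merged[rt_col])
        dp_ranks = rankdata(-merged[dp_col])
        for group in GROUPS:
            mask = (merged["group"] == group).to_numpy()
            if mask.sum() >= 4 and np.ptp(rt_ranks[mask]) > 0:
                slope = linregress(rt_ranks[mask], dp_ranks[mask]).slope
            else:
                slope = float("nan")
            row[f"slope_{group}"] = float(slope)
        rows.append(row)
    return pd.DataFrame(rows)
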