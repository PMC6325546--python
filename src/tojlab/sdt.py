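"""Signal-detection d' for TOJ data under the SD = 0.5 z-convention.

A "hit" is a left-first response when the left side actually changed first
(positive asynchrony); a "false alarm" is a left-first response when the
left side changed second (negative asynchrony). Sensitivity is

    d' = Z(hits) - Z(false alarms),   Z(p) = 0.5 * Phi^{-1}(p),

i.e. z-scores on a normal with SD 0.5, so that d' = 0.67 corresponds to
unbiased 75% correct. Extreme proportions are corrected by assuming half a
trial: 0 hits/FAs out of n become 0.5/n and n out of n become (n-0.5)/n,
for pool sizes n = 20 (single asynchrony magnitude) or n = 60 (all three
magnitudes pooled).

Each participant yields 16 d' values: 12 at each (motion type x initial
directions x |asynchrony| in {67, 133, 200} ms) cell, pairing the +X trials
(hits, 20) with the -X trials (false alarms, 20), plus 4 pooled values per
(motion type x initial directions) aggregating the 60 positive and 60
negative trials. Zero-asynchrony trials never enter d'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import DomainError, ParameterError, ValidationError
from .trial_model import CONDITIONS, TRIALS_PER_CELL, ParticipantSet

#: SD of the z-distribution used by this analysis.
Z_SD = 0.5

#: Pool sizes permitted by the extreme-count correction.
ALLOWED_POOLS = (20, 60)

#: asynchrony classes of the 16 entries: three magnitudes plus "pooled"
ASYNCHRONY_CLASSES = (67, 133, 200, "pooled")

EntryKey = Tuple[str, str, Union[int, str]]


def z_half(p):
    """z-score of proportion ``p`` on the SD-0.5 scale: 0.5 * Phi^{-1}(p).

    Strictly increasing in p; raises :class:`DomainError` outside (0, 1)
    (the extreme-count correction must be applied upstream).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise DomainError("proportion must lie strictly in (0, 1); "
                          "apply the extreme-count correction first")
    out = Z_SD * ndtri(arr)
    return out if out.ndim else float(out)


def correct_extreme(count: int, n: int, allow_any_n: bool = False) -> float:
    """Proportion ``count/n`` with the half-trial correction at 0 and n.

    Only pool sizes 20 and 60 occur in the canonical design; other sizes
    raise :class:`ParameterError` unless ``allow_any_n`` is set (used for
    simulation-scale checks).
    """
    if n not in ALLOWED_POOLS and not allow_any_n:
        raise ParameterError(
            f"pool size {n} not in {ALLOWED_POOLS}; pass allow_any_n=True "
            "to permit non-canonical pools")
    if not 0 <= count <= n:
        raise DomainError(f"count {count} outside [0, {n}]")
    if count == 0:
        return 0.5 / n
    if count == n:
        return (n - 0.5) / n
    return count / n


def dprime(hit_prop: float, fa_prop: float) -> float:
    """d' = z_half(hits) - z_half(false alarms); antisymmetric under swap."""
    return z_half(hit_prop) - z_half(fa_prop)


@dataclass(frozen=True)
class DPrimeEntry:
    d: float
    z_hits: float
    z_false_alarms: float
    hit_prop: float
    fa_prop: float
    n_pool: int


@dataclass
class DPrimeTable:
    """The 16 d' values of one participant (12 per-asynchrony + 4 pooled)."""

    participant_id: str
    group: str
    entries: Dict[EntryKey, DPrimeEntry]

    def __post_init__(self):
        expected = {(m, d, c) for m, d in CONDITIONS for c in ASYNCHRONY_CLASSES}
        if set(self.entries) != expected:
            raise ValidationError(
                f"expected the 16 canonical entries, got {len(self.entries)}")
        for key, e in self.entries.items():
            if not np.isfinite(e.d):
                raise ValidationError(f"non-finite d' in entry {key}")

    def as_frame(self) -> pd.DataFrame:
        rows = [{
            "participant_id": self.participant_id, "group": self.group,
            "motion_type": m, "initial_directions": d,
            "asynchrony_class": str(c), "dprime": e.d,
            "z_hits": e.z_hits, "z_false_alarms": e.z_false_alarms,
            "hit_prop": e.hit_prop, "fa_prop": e.fa_prop, "n_pool": e.n_pool,
        } for (m, d, c), e in sorted(self.entries.items(), key=lambda kv: (
            kv[0][0], kv[0][1], str(kv[0][2])))]
        return pd.DataFrame(rows)


def _counts(trials: pd.DataFrame, allow_any_n: bool):
    """Tally left-first counts per (pid, cell, magnitude, sign) and pooled."""
    nz = trials[trials["asynchrony_ms"] != 0].copy()
    nz["magnitude"] = nz["asynchrony_ms"].abs()
    nz["positive"] = nz["asynchrony_ms"] > 0
    nz["left_first"] = nz["response"] == "left_first"
    per = (nz.groupby(["participant_id", "group", "motion_type",
                       "initial_directions", "magnitude", "positive"],
                      observed=True)["left_first"]
           .agg(["sum", "count"]).reset_index())
    pooled = (nz.groupby(["participant_id", "group", "motion_type",
                          "initial_directions", "positive"],
                         observed=True)["left_first"]
              .agg(["sum", "count"]).reset_index())
    if not allow_any_n:
        if (per["count"] != TRIALS_PER_CELL).any():
            bad = per[per["count"] != TRIALS_PER_CELL]
            raise ValidationError(
                "per-asynchrony pools must hold exactly "
                f"{TRIALS_PER_CELL} trials; offending pools:\n"
                f"{bad.to_string(index=False)}")
    return per, pooled


def dprime_frame(trials: ParticipantSet, allow_any_n: bool = False) -> pd.DataFrame:
    """Long-format d' table for every participant in ``trials``.

    One row per participant x 16 entries with columns participant_id,
    group, motion_type, initial_directions, asynchrony_class ("67", "133",
    "200", "pooled"), dprime, z_hits, z_false_alarms, hit_prop, fa_prop,
    n_pool. Operates on analysis-block trials only.
    """
    analysis = trials.analysis_trials
    per, pooled = _counts(analysis, allow_any_n)

    def _build(df, class_col):
        idx = ["participant_id", "group", "motion_type", "initial_directions"]
        if class_col:
            idx = idx + [class_col]
        wide = df.pivot_table(index=idx, columns="positive",
                              values=["sum", "count"], aggfunc="first")
        if (True not in wide["sum"].columns) or (False not in wide["sum"].columns):
            raise ValidationError("missing positive or negative trials in a cell")
        if wide.isna().any().any():
            raise ValidationError("missing cells: some (condition, sign) pools absent")
        out = wide.reset_index()
        hits_n = wide[("count", True)].to_numpy(int)
        fa_n = wide[("count", False)].to_numpy(int)
        hits = wide[("sum", True)].to_numpy(int)
        fas = wide[("sum", False)].to_numpy(int)
        hp = np.array([correct_extreme(h, n, allow_any_n=allow_any_n)
                       for h, n in zip(hits, hits_n)])
        fp = np.array([correct_extreme(f, n, allow_any_n=allow_any_n)
                       for f, n in zip(fas, fa_n)])
        res = pd.DataFrame({
            "participant_id": out["participant_id"],
            "group": out["group"],
            "motion_type": out["motion_type"],
            "initial_directions": out["initial_directions"],
            "asynchrony_class": (out[class_col].astype(int).astype(str)
                                 if class_col else "pooled"),
            "z_hits": z_half(hp), "z_false_alarms": z_half(fp),
            "hit_prop": hp, "fa_prop": fp, "n_pool": hits_n,
        })
        res["dprime"] = res["z_hits"] - res["z_false_alarms"]
        return res

    frame = pd.concat([_build(per, "magnitude"), _build(pooled, None)],
                      ignore_index=True)
    cols = ["participant_id", "group", "motion_type", "initial_directions",
            "asynchrony_class", "dprime", "z_hits", "z_false_alarms",
            "hit_prop", "fa_prop", "n_pool"]
    return (frame[cols]
            .sort_values(["participant_id", "motion_type",
                          "initial_directions", "asynchrony_class"],
                         kind="stable")
            .reset_index(drop=True))


def dprime_table(trials: ParticipantSet, participant_id: str,
                 allow_any_n: bool = False) -> DPrimeTable:
    """The 16-entry :class:`DPrimeTable` of one participant."""
    sub = trials.subset([str(participant_id)])
    if sub.trials.empty:
        raise ValidationError(f"no trials for participant {participant_id!r}")
    frame = dprime_frame(sub, allow_any_n=allow_any_n)
    group = frame["group"].iloc[0]
    entries = {}
    for _, row in frame.iterrows():
        cls = "pooled" if row["asynchrony_class"] == "pooled" else int(row["asynchrony_class"])
        entries[(row["motion_type"], row["initial_directions"], cls)] = DPrimeEntry(
            d=float(row["dprime"]), z_hits=float(row["z_hits"]),
            z_false_alarms=float(row["z_false_alarms"]),
            hit_prop=float(row["hit_prop"]), fa_prop=float(row["fa_prop"]),
            n_pool=int(row["n_pool"]))
    return DPrimeTable(participant_id=str(participant_id), group=group,
                       entries=entries)
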