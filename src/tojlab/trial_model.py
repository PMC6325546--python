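"""Trial-level data model and delimited-text I/O for the TOJ experiment.

One trial of the two-alternative temporal-order-judgment (TOJ) task is a row:
a participant watched bilateral dynamic plaids that reversed direction with a
signed asynchrony X (negative = left lagging, the right side changed first;
positive = left leading) and pressed "left first" or "right first". The
analysis design crosses 2 motion types (radial, rotational) x 2 initial
directions (same, opposite) x 7 asynchronies (-200..+200 ms in ~67 ms steps),
with 20 analysis repeats per cell = 560 analysis trials per participant,
collected in five 112-trial blocks after one practice block (block 0).

The canonical on-disk format is a UTF-8 CSV with the columns in ``COLUMNS``,
"." decimal separator and a newline-terminated final row. Frame-quantized
asynchronies (e.g. 66.67 ms at a 60 Hz refresh) are snapped to the nominal
printed values on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

GROUPS = ("percussion", "brass", "color_guard")
MOTION_TYPES = ("radial", "rotational")
INITIAL_DIRECTIONS = ("same", "opposite")
RESPONSES = ("left_first", "right_first")

#: Nominal signed asynchronies in ms; negative = left-lagging (right changed
#: first), positive = left-leading.
NOMINAL_ASYNCHRONIES_MS = (-200, -133, -67, 0, 67, 133, 200)
NONZERO_MAGNITUDES_MS = (67, 133, 200)

#: The four motion-stimulus conditions, in canonical order.
CONDITIONS = tuple((m, d) for m in MOTION_TYPES for d in INITIAL_DIRECTIONS)

TRIALS_PER_CELL = 20
ANALYSIS_BLOCKS = 5
N_CELLS = len(CONDITIONS) * len(NOMINAL_ASYNCHRONIES_MS)          # 28
TRIALS_PER_PARTICIPANT = N_CELLS * TRIALS_PER_CELL                # 560
NONZERO_TRIALS_PER_PARTICIPANT = TRIALS_PER_PARTICIPANT - len(CONDITIONS) * TRIALS_PER_CELL  # 480

COLUMNS = [
    "participant_id",
    "group",
    "motion_type",
    "initial_directions",
    "asynchrony_ms",
    "response",
    "designated_correct",
    "rt_ms",
    "block",
]

# tolerance absorbing frame-quantized inputs such as 66.67 ms
_ASYNC_SNAP_TOL_MS = 1.0


@dataclass
class ParticipantSet:
    """A validated collection of trials plus provenance metadata.

    ``trials`` holds one row per trial with the columns in ``COLUMNS``;
    ``provenance`` is free-form (source file, generator seeds). Practice
    trials (block 0) are retained but excluded from every statistic via
    :attr:`analysis_trials`.
    """

    trials: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: Mapping | None = None,
                   validate_design: bool = True) -> "ParticipantSet":
        """Validate ``frame`` against the data-model invariants and wrap it.

        ``validate_design=False`` skips the 20-trials-per-cell design check
        (used for deliberately overridden designs, e.g. simulation-scale
        convergence checks); the per-row invariants always apply.
        """
        trials = _validate(frame, validate_design=validate_design)
        return cls(trials=trials, provenance=dict(provenance or {}))

    @property
    def participants(self) -> pd.DataFrame:
        """One row per participant: participant_id, group."""
        if self.trials.empty:
            return pd.DataFrame(columns=["participant_id", "group"])
        out = (self.trials[["participant_id", "group"]]
               .drop_duplicates()
               .sort_values("participant_id", kind="stable")
               .reset_index(drop=True))
        return out

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def analysis_trials(self) -> pd.DataFrame:
        """All trials from post-practice blocks (block > 0)."""
        return self.trials[self.trials["block"] > 0]

    def subset(self, participant_ids) -> "ParticipantSet":
        """Restrict to the given participants, keeping provenance."""
        keep = self.trials["participant_id"].isin(list(participant_ids))
        return ParticipantSet(trials=self.trials[keep].reset_index(drop=True),
                              provenance=dict(self.provenance))


def _snap_asynchronies(values: pd.Series) -> pd.Series:
    """Snap frame-quantized asynchronies to the nominal grid (or raise)."""
    arr = values.to_numpy(dtype=float)
    nominal = np.asarray(NOMINAL_ASYNCHRONIES_MS, dtype=float)
    dist = np.abs(arr[:, None] - nominal[None, :])
    nearest = dist.argmin(axis=1)
    off_grid = dist[np.arange(len(arr)), nearest] > _ASYNC_SNAP_TOL_MS
    if off_grid.any():
        bad = sorted(set(np.round(arr[off_grid], 3)))
        raise ValidationError(
            f"asynchrony_ms values not within {_ASYNC_SNAP_TOL_MS} ms of the "
            f"nominal grid {NOMINAL_ASYNCHRONIES_MS}: {bad}")
    return pd.Series(nominal[nearest].astype(int), index=values.index)


def _validate(frame: pd.DataFrame, validate_design: bool = True) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in frame.columns]
    extra = [c for c in frame.columns if c not in COLUMNS]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns {missing}")
        if extra:
            parts.append(f"unexpected columns {extra}")
        raise FormatError("; ".join(parts))

    df = frame[COLUMNS].copy()
    if df.empty:
        df = df.astype({"participant_id": str, "asynchrony_ms": int,
                        "rt_ms": float, "block": int,
                        "designated_correct": bool})
        return df.reset_index(drop=True)

    df["participant_id"] = df["participant_id"].astype(str)
    for col, allowed in (("group", GROUPS), ("motion_type", MOTION_TYPES),
                         ("initial_directions", INITIAL_DIRECTIONS),
                         ("response", RESPONSES)):
        df[col] = df[col].astype(str)
        bad = sorted(set(df[col]) - set(allowed))
        if bad:
            raise ValidationError(f"invalid {col} values {bad}; allowed {allowed}")

    df["asynchrony_ms"] = _snap_asynchronies(pd.to_numeric(df["asynchrony_ms"]))
    df["rt_ms"] = pd.to_numeric(df["rt_ms"]).astype(float)
    if not (df["rt_ms"] > 0).all():
        n_bad = int((~(df["rt_ms"] > 0)).sum())
        raise ValidationError(f"rt_ms must be > 0; {n_bad} offending rows")

    df["block"] = pd.to_numeric(df["block"]).astype(int)
    if (df["block"] < 0).any():
        raise ValidationError("block must be >= 0 (0 = practice)")

    if df["designated_correct"].dtype != bool:
        df["designated_correct"] = df["designated_correct"].map(
            {True: True, False: False, "True": True, "False": False,
             "true": True, "false": False, 1: True, 0: False, "1": True,
             "0": False})
        if df["designated_correct"].isna().any():
            raise ValidationError("designated_correct must be boolean")
        df["designated_correct"] = df["designated_correct"].astype(bool)

    # sign rule: for X != 0, correct <=> (left_first <=> X > 0)
    nz = df["asynchrony_ms"] != 0
    expected = (df.loc[nz, "response"] == "left_first") == (df.loc[nz, "asynchrony_ms"] > 0)
    mismatch = df.loc[nz][expected != df.loc[nz, "designated_correct"]]
    if len(mismatch):
        rows = mismatch.index.tolist()[:10]
        raise ValidationError(
            f"designated_correct disagrees with the asynchrony sign rule on "
            f"{len(mismatch)} rows (first rows: {rows})")

    # one group per participant
    ngroups = df.groupby("participant_id")["group"].nunique()
    multi = ngroups[ngroups > 1].index.tolist()
    if multi:
        raise ValidationError(f"participants mapped to multiple groups: {multi}")

    if validate_design:
        analysis = df[df["block"] > 0]
        counts = analysis.groupby(
            ["participant_id", "motion_type", "initial_directions", "asynchrony_ms"],
            observed=True).size()
        bad_cells = counts[counts != TRIALS_PER_CELL]
        # a participant may also be missing cells entirely
        n_cells = counts.groupby(level="participant_id").size()
        missing_cells = n_cells[n_cells != N_CELLS].index.tolist()
        if len(bad_cells) or missing_cells:
            named = [f"{idx} -> {int(n)} trials (expected {TRIALS_PER_CELL})"
                     for idx, n in bad_cells.items()]
            msg = "design violation: " + "; ".join(named[:20])
            if missing_cells:
                msg += f"; participants with missing cells: {missing_cells}"
            raise ValidationError(msg)

    return df.reset_index(drop=True)


def read_trials(path, dialect: str = "csv", validate_design: bool = True) -> ParticipantSet:
    """Read a trials table from ``path`` and validate it.

    Raises :class:`FormatError` for missing/extra columns and
    :class:`ValidationError` for invariant violations (off-grid
    asynchronies, sign-rule breaches, wrong cell counts).
    """
    if dialect != "csv":
        raise FormatError(f"unsupported dialect {dialect!r}; only 'csv'")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path)
    if frame.empty and list(frame.columns) != COLUMNS:
        # header-only file with wrong header still errors
        pass
    return ParticipantSet.from_frame(
        frame, provenance={"source": str(path)}, validate_design=validate_design)


def write_trials(data: ParticipantSet, path) -> Path:
    """Write ``data`` to ``path`` as canonical CSV; returns the path.

    Rows are ordered by (participant, block, original trial order) and
    floats are rendered with three decimals so write -> read -> write is
    byte-identical.
    """
    path = Path(path)
    df = data.trials.copy()
    df = df.sort_values(["participant_id", "block"], kind="stable")
    df = df[COLUMNS]
    df.to_csv(path, index=False, float_format="%.3f", lineterminator="\n")
    return path
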