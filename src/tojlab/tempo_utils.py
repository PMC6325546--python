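"""Deterministic conversions between asynchronies, musical subdivisions,
and color-guard rotation angles.

A marching tempo of ``tempo`` beats/min subdivided into ``subdivision``
notes per beat (1 = quarter, 2 = 8th, 4 = 16th, 8 = 32nd) yields note
durations of 60000/(tempo * subdivision) ms and temporal frequencies of
tempo * subdivision / 60 Hz. Color-guard rifles rotating a full 360 deg
every 500 ms (0.72 deg/ms) turn a temporal asynchrony into an angular
mismatch of asynchrony * rotation_rate degrees; antiphase (180 deg) occurs
at 180/rotation_rate ms.

All functions return unrounded values; rounding to the printed precision
(two decimals for durations/frequencies, whole degrees for angles) is a
reporting-layer concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError

#: default rifle rotation rate: 360 deg per 500 ms
DEFAULT_ROTATION_RATE_DEG_PER_MS = 360.0 / 500.0

ALLOWED_SUBDIVISIONS = (1, 2, 4, 8)

SUBDIVISION_NAMES = {1: "quarter", 2: "8th", 4: "16th", 8: "32nd"}


@dataclass(frozen=True)
class TempoContext:
    """Tempo, subdivision, and rotation rate for the conversions."""

    tempo: float                                   # beats/min
    subdivision: int = 1                           # notes per beat
    rotation_rate: float = DEFAULT_ROTATION_RATE_DEG_PER_MS  # deg/ms

    def __post_init__(self):
        if not self.tempo > 0:
            raise ParameterError("tempo must be > 0")
        if self.subdivision not in ALLOWED_SUBDIVISIONS:
            raise ParameterError(
                f"subdivision must be one of {ALLOWED_SUBDIVISIONS}")
        if not self.rotation_rate > 0:
            raise ParameterError("rotation_rate must be > 0")


def note_duration_ms(ctx: TempoContext) -> float:
    """Duration of one note at this tempo/subdivision: 60000/tempo/subdivision."""
    return 60000.0 / ctx.tempo / ctx.subdivision


def note_frequency_hz(ctx: TempoContext) -> float:
    """Temporal frequency of the subdivision: tempo * subdivision / 60."""
    return ctx.tempo * ctx.subdivision / 60.0


def threshold_to_hz(threshold_ms: float) -> float:
    """Temporal frequency equivalent of a TOJ threshold: 1000/threshold."""
    if not threshold_ms > 0:
        raise ParameterError("threshold must be > 0 ms")
    return 1000.0 / threshold_ms


def angular_mismatch_deg(asynchrony_ms: float,
                         ctx: TempoContext | None = None) -> float:
    """Angular mismatch between rotating rifles at this asynchrony."""
    if asynchrony_ms < 0:
        raise ParameterError("asynchrony must be >= 0 ms")
    rate = ctx.rotation_rate if ctx else DEFAULT_ROTATION_RATE_DEG_PER_MS
    return asynchrony_ms * rate


def antiphase_asynchrony_ms(ctx: TempoContext | None = None) -> float:
    """Asynchrony producing a 180-degree (antiphase) mismatch."""
    rate = ctx.rotation_rate if ctx else DEFAULT_ROTATION_RATE_DEG_PER_MS
    return 180.0 / rate


def tempo_grid(tempos=(180.0, 120.0)) -> pd.DataFrame:
    """The note-duration / temporal-frequency grid at the given tempos.

    One row per (tempo, subdivision) with unrounded duration and frequency
    columns — the library-level constant behind the printed conversion
    table.
    """
    rows = []
    for tempo in tempos:
        for sub in ALLOWED_SUBDIVISIONS:
            ctx = TempoContext(tempo=tempo, subdivision=sub)
            rows.append({
                "tempo_bpm": tempo,
                "subdivision": sub,
                "note": SUBDIVISION_NAMES[sub],
                "duration_ms": note_duration_ms(ctx),
                "frequency_hz": note_frequency_hz(ctx),
            })
    return pd.DataFrame(rows)
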