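"""Group psychometric functions and 75% JND thresholds.

For each (motion type x initial directions x group) combination the group
psychometric function plots, against the seven signed asynchronies X, the
median across participants of each participant's proportion of left-first
responses (20 trials per participant per X). An unweighted least-squares
procedure fits the 2-parameter sigmoid

    p(X) = 1 / (1 + exp(-K (X - Xo)))

where K (1/ms) is the slope and Xo (ms) the midpoint. The 75% threshold
(just-noticeable difference) is half the asynchrony change that moves the
left-first rate from 0.25 to 0.75, which for this sigmoid is ln(3)/K; its
standard error follows from SE(K) by the delta method,
SE(thr) = ln(3) SE(K) / K^2. Goodness of fit is the Pearson correlation r
between observed and fitted ordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, brentq, curve_fit
from scipy.special import expit, logit
from scipy.stats import pearsonr

from .errors import DomainError, FitError, ValidationError
from .trial_model import CONDITIONS, GROUPS, ParticipantSet

LN3 = math.log(3.0)


def logistic(x, k, xo):
    """The fitted sigmoid 1 / (1 + exp(-k (x - xo)))."""
    return expit(k * (np.asarray(x, dtype=float) - xo))


@dataclass
class PsychometricPoints:
    """Group median left-first proportions at the seven asynchronies."""

    motion_type: str
    initial_directions: str
    group: str
    x: np.ndarray
    p_left: np.ndarray
    n_participants: int

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.p_left = np.asarray(self.p_left, dtype=float)
        if self.x.shape != self.p_left.shape:
            raise ValidationError("x and p_left must have matching shape")
        if np.any(self.p_left < 0) or np.any(self.p_left > 1):
            raise ValidationError("p_left must lie in [0, 1]")


@dataclass
class PsychometricFit:
    """Fitted slope/midpoint with goodness of fit and derived threshold."""

    k: float                 # slope, 1/ms
    xo: float                # midpoint, ms
    k_se: float
    xo_se: float
    r: float                 # Pearson r, observed vs fitted
    r2: float
    threshold_ms: float      # ln(3)/K
    threshold_se_ms: float   # delta method


def build_points(trials: ParticipantSet, condition: Tuple[str, str],
                 group: str) -> PsychometricPoints:
    """Median-across-participants left-first proportion per asynchrony.

    Each participant contributes, per X, the proportion of left-first
    responses over their analysis trials in that cell; the group ordinate
    is the median of those proportions.
    """
    motion, dirs = condition
    df = trials.analysis_trials
    sel = df[(df["motion_type"] == motion)
             & (df["initial_directions"] == dirs)
             & (df["group"] == group)]
    if sel.empty:
        raise ValidationError(
            f"no trials for group {group!r}, condition {condition}")
    props = (sel.assign(left=sel["response"] == "left_first")
             .groupby(["participant_id", "asynchrony_ms"], observed=True)["left"]
             .mean().unstack("asynchrony_ms"))
    if props.isna().any().any():
        raise ValidationError(
            f"some participants lack trials at some asynchronies in {condition}")
    med = props.median(axis=0)
    x = med.index.to_numpy(dtype=float)
    order = np.argsort(x)
    return PsychometricPoints(
        motion_type=motion, initial_directions=dirs, group=group,
        x=x[order], p_left=med.to_numpy(dtype=float)[order],
        n_participants=props.shape[0])


def _initial_guess(x: np.ndarray, p: np.ndarray) -> Tuple[float, float]:
    """Xo0 = x nearest p=0.5; K0 from a logit-linear regression."""
    xo0 = float(x[np.argmin(np.abs(p - 0.5))])
    pc = np.clip(p, 0.01, 0.99)
    slope = np.polyfit(x, logit(pc), 1)[0]
    k0 = float(slope) if slope > 0 else 1e-3
    return max(k0, 1e-6), xo0


_K0_GRID = (1e-4, 1e-3, 5e-3, 0.01, 0.02, 0.05, 0.1)


def fit_sigmoid(points: PsychometricPoints) -> PsychometricFit:
    """Unweighted least-squares fit of the 2-parameter sigmoid.

    Starts from the documented initialization (midpoint at the ordinate
    closest to 0.5, slope from a logit-linear regression) and falls back to
    a bounded grid of slope restarts; raises :class:`FitError` with
    diagnostics if no start converges to a positive slope.
    """
    x, p = points.x, points.p_left
    k0, xo0 = _initial_guess(x, p)
    starts = [(k0, xo0)] + [(kk, xx) for kk in _K0_GRID for xx in (xo0, 0.0)]
    best = None
    errors = []
    for start in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, pcov = curve_fit(logistic, x, p, p0=list(start),
                                       maxfev=20000)
        except Exception as exc:  # non-convergence for this start
            errors.append(f"start {start}: {exc}")
            continue
        if not np.isfinite(popt).all() or popt[0] <= 0:
            errors.append(f"start {start}: non-positive or non-finite slope")
            continue
        resid = float(np.sum((p - logistic(x, *popt)) ** 2))
        if best is None or resid < best[2] - 1e-15:
            best = (popt, pcov, resid)
        if resid < 1e-12:
            break
    if best is None:
        raise FitError("sigmoid fit failed to converge from all restarts",
                       diagnostics={"x": x.tolist(), "p_left": p.tolist(),
                                    "errors": errors})
    popt, pcov, _ = best
    k, xo = float(popt[0]), float(popt[1])
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    k_se = float(se[0]) if np.isfinite(se[0]) else float("nan")
    xo_se = float(se[1]) if np.isfinite(se[1]) else float("nan")
    fitted = logistic(x, k, xo)
    if np.ptp(fitted) < 1e-12 or np.ptp(p) < 1e-12:
        r = float("nan")
    else:
        r = float(pearsonr(p, fitted)[0])
    thr, thr_se = threshold_from_slope(k, k_se)
    return PsychometricFit(k=k, xo=xo, k_se=k_se, xo_se=xo_se, r=r,
                           r2=r * r if np.isfinite(r) else float("nan"),
                           threshold_ms=thr, threshold_se_ms=thr_se)


def threshold_from_slope(k: float, k_se: float | None = None
                         ) -> Tuple[float, float]:
    """75% threshold ln(3)/K and its delta-method SE.

    Half the span between the 25% and 75% points of the logistic:
    logit(0.75) - logit(0.25) = 2 ln 3, so the half-span is ln(3)/K.
    """
    if not k > 0:
        raise DomainError("threshold requires a positive slope K")
    thr = LN3 / k
    if k_se is None or not np.isfinite(k_se):
        return thr, float("nan")
    return thr, LN3 * k_se / k ** 2


def threshold_from_fit(fit: PsychometricFit) -> Tuple[float, float]:
    """Threshold (ms) and SE recomputed from a fit's slope."""
    return threshold_from_slope(fit.k, fit.k_se)


def threshold_by_scanning(k: float, xo: float) -> float:
    """Brute-force threshold: locate p = 0.25 and 0.75 on the fitted curve
    numerically and halve the span (independent check of ln(3)/K)."""
    if not k > 0:
        raise DomainError("scanning requires a positive slope K")
    span = 10.0 * LN3 / k
    lo = brentq(lambda x: logistic(x, k, xo) - 0.25, xo - span, xo)
    hi = brentq(lambda x: logistic(x, k, xo) - 0.75, xo, xo + span)
    return (hi - lo) / 2.0


def fit_all(trials: ParticipantSet) -> pd.DataFrame:
    """Fit every (group x condition) present; long-format results table.

    Columns: group, motion_type, initial_directions, n_participants, k, xo,
    k_se, xo_se, r, r2, threshold_ms, threshold_se_ms.
    """
    rows = []
    present = set(trials.participants["group"])
    for group in GROUPS:
        if group not in present:
            continue
        for condition in CONDITIONS:
            pts = build_points(trials, condition, group)
            fit = fit_sigmoid(pts)
            rows.append({
                "group": group, "motion_type": condition[0],
                "initial_directions": condition[1],
                "n_participants": pts.n_participants,
                "k": fit.k, "xo": fit.xo, "k_se": fit.k_se, "xo_se": fit.xo_se,
                "r": fit.r, "r2": fit.r2, "threshold_ms": fit.threshold_ms,
                "threshold_se_ms": fit.threshold_se_ms,
            })
    return pd.DataFrame(rows)
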