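"""Cohort-level alarm performance, circadian analysis and the LDH model.

Alarm metrics follow the conventions of device-alarm validation studies:

* **sensitivity** — fraction of thrombosis snapshots with at least one
  combined alarm at or before the diagnosis time;
* **specificity** — fraction of control logfile periods with no alarm at all
  (a period with any flagged sample counts as one false positive, regardless
  of flagged duration);
* **early warning** — signed days from the first alarm to the diagnosis
  (negative = alarm precedes diagnosis);
* **false-positive burden** — patient-years of control monitoring per
  false-positive period (1 patient-year = 365.25 days).

The module also provides the circadian-rhythm test (dominant spectral period
within 24 h ± 30 min), the sudden-vs-gradual build-up classifier (smoothed
power rising by more than 0.75 W within a short horizon) and the two-term
exponential model of the hemolysis marker LDH in the days before diagnosis.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .errors import FitError, InsufficientDataError, UndefinedWarningError
from .io import DAYS_PER_PATIENT_YEAR, SECONDS_PER_DAY, Snapshot
from .tracking import DetectionSeries

#: Dominant-period band accepted as circadian, hours.
CIRCADIAN_BAND_H = (23.5, 24.5)

#: Power rise within the sudden-build-up horizon that separates sudden from
#: gradual signatures, W.
SUDDEN_RISE_W = 0.75


# ---------------------------------------------------------------------------
# alarm metrics


def snapshot_detected(
    series: DetectionSeries, event_time
) -> tuple[bool, pd.Timestamp | None]:
    """Did any combined alarm occur at or before the diagnosis time?

    Returns ``(detected, first_flag_time)``; flags strictly after the event
    never count (post-diagnosis detections are not early warnings).
    """
    if len(series) == 0:
        raise InsufficientDataError("empty detection series")
    first = series.first_flag_time(before=event_time)
    return first is not None, first


def sensitivity(snapshot_results: Sequence[bool]) -> float:
    """Percent of thrombosis snapshots detected pre-diagnosis (1 decimal)."""
    results = list(snapshot_results)
    if not results:
        raise InsufficientDataError("sensitivity of an empty snapshot cohort")
    return round(100.0 * sum(map(bool, results)) / len(results), 1)


def specificity(control_results: Sequence[bool]) -> float:
    """Percent of control periods free of any alarm (1 decimal).

    ``control_results`` holds one boolean per period: True = at least one
    alarm (false positive).
    """
    results = list(control_results)
    if not results:
        raise InsufficientDataError("specificity of an empty control cohort")
    clean = sum(not bool(r) for r in results)
    return round(100.0 * clean / len(results), 1)


def accuracy(
    snapshot_results: Sequence[bool], control_results: Sequence[bool]
) -> float:
    """Percent correct over snapshots + control periods pooled (1 decimal).

    Standard (TP + TN) / (P + N) with snapshots as positives and control
    periods as negatives.
    """
    snaps = list(snapshot_results)
    ctrls = list(control_results)
    if not snaps or not ctrls:
        raise InsufficientDataError("accuracy requires both cohorts")
    tp = sum(map(bool, snaps))
    tn = sum(not bool(r) for r in ctrls)
    return round(100.0 * (tp + tn) / (len(snaps) + len(ctrls)), 1)


def early_warning(first_flag_time, event_time) -> float:
    """Signed days from first alarm to diagnosis (negative = before)."""
    if first_flag_time is None:
        raise UndefinedWarningError("no detection — early warning undefined")
    delta = pd.Timestamp(first_flag_time) - pd.Timestamp(event_time)
    return delta.total_seconds() / SECONDS_PER_DAY


def fp_interval(
    control_results: Sequence[bool], total_duration_days: float
) -> float:
    """Patient-years of control monitoring per false-positive period.

    Returns ``inf`` when no false positive was observed (reported downstream
    as "none observed").
    """
    if total_duration_days <= 0:
        raise InsufficientDataError("total control duration must be positive")
    n_fp = sum(map(bool, control_results))
    years = total_duration_days / DAYS_PER_PATIENT_YEAR
    return math.inf if n_fp == 0 else years / n_fp


@dataclass
class PerformanceReport:
    """Cohort-level alarm performance summary."""

    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    early_warnings_days: list[float]
    fp_periods: list[tuple[str, float]]  # (period id, flagged duration days)
    patient_years_control: float
    fp_interval_py: float
    n_snapshots: int = 0
    n_control_periods: int = 0

    @property
    def median_early_warning_days(self) -> float | None:
        if not self.early_warnings_days:
            return None
        return float(np.median(self.early_warnings_days))

    def to_dict(self) -> dict:
        return {
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
            "early_warnings_days": [round(d, 3) for d in self.early_warnings_days],
            "median_early_warning_days": self.median_early_warning_days,
            "fp_periods": [
                {"period_id": pid, "flagged_days": round(d, 3)}
                for pid, d in self.fp_periods
            ],
            "patient_years_control": round(self.patient_years_control, 3),
            "fp_interval_patient_years": (
                None if math.isinf(self.fp_interval_py) else round(self.fp_interval_py, 3)
            ),
            "n_snapshots": self.n_snapshots,
            "n_control_periods": self.n_control_periods,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_cohort(
    snapshot_runs: Sequence[tuple[DetectionSeries, pd.Timestamp]],
    control_runs: Sequence[tuple[str, DetectionSeries, float]],
) -> PerformanceReport:
    """Assemble a :class:`PerformanceReport` from per-stream detector runs.

    Parameters
    ----------
    snapshot_runs
        ``(detection series, event_time)`` per thrombosis snapshot.
    control_runs
        ``(period id, detection series, duration_days)`` per control period.
    """
    detections = [snapshot_detected(series, ev) for series, ev in snapshot_runs]
    det_flags = [d for d, _ in detections]
    warnings = [
        early_warning(first, ev)
        for (d, first), (_, ev) in zip(detections, snapshot_runs)
        if d
    ]
    fp_flags = [series.n_flagged > 0 for _, series, _ in control_runs]
    fp_periods = [
        (pid, series.flagged_duration_days())
        for pid, series, _ in control_runs
        if series.n_flagged > 0
    ]
    total_days = sum(dur for _, _, dur in control_runs)
    return PerformanceReport(
        sensitivity_pct=sensitivity(det_flags),
        specificity_pct=specificity(fp_flags),
        accuracy_pct=accuracy(det_flags, fp_flags),
        early_warnings_days=sorted(warnings),
        fp_periods=fp_periods,
        patient_years_control=total_days / DAYS_PER_PATIENT_YEAR,
        fp_interval_py=fp_interval(fp_flags, total_days),
        n_snapshots=len(snapshot_runs),
        n_control_periods=len(control_runs),
    )


# ---------------------------------------------------------------------------
# circadian analysis


@dataclass(frozen=True)
class CircadianResult:
    """Dominant spectral period of a power record."""

    dominant_period_h: float
    is_circadian: bool
    band_h: tuple[float, float] = CIRCADIAN_BAND_H


def detect_circadian(data, min_days: float = 2.0) -> CircadianResult:
    """Test a power record for a circadian (≈24 h) rhythm.

    The power series is linearly detrended and Hann-windowed (suppressing
    leakage from slow ramps), its discrete spectrum computed, and the
    dominant period taken as the reciprocal of the frequency with maximum
    spectral power, restricted to periods no longer than half the record.
    The record is circadian when that period lies within 24 h ± 30 min.
    """
    frame = data.frame if hasattr(data, "frame") else data
    t = frame["timestamp"]
    if len(frame) < 4:
        raise InsufficientDataError("record too short for spectral analysis")
    span_days = (t.iloc[-1] - t.iloc[0]).total_seconds() / SECONDS_PER_DAY
    if span_days < min_days:
        raise InsufficientDataError(
            f"record spans {span_days:.2f} d < required {min_days:g} d"
        )
    power = frame["power_w"].to_numpy(float)
    dt_h = float(np.median(np.diff(t).astype("timedelta64[s]").astype(float))) / 3600.0

    x = signal.detrend(power, type="linear")
    x = x * np.hanning(len(x))
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=dt_h)  # cycles per hour

    record_h = span_days * 24.0
    valid = freqs >= 2.0 / record_h  # period ≤ half the record
    if not valid.any():
        raise InsufficientDataError("no resolvable frequency in record")
    idx = np.flatnonzero(valid)[np.argmax(spec[valid])]
    period_h = 1.0 / freqs[idx]
    lo, hi = CIRCADIAN_BAND_H
    return CircadianResult(
        dominant_period_h=float(period_h), is_circadian=bool(lo <= period_h <= hi)
    )


# ---------------------------------------------------------------------------
# build-up signature classification


def _trailing_mean(t_s: np.ndarray, x: np.ndarray, window_s: float) -> np.ndarray:
    """Unweighted mean of x over the trailing window at each point."""
    out = np.empty_like(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    start = np.searchsorted(t_s, t_s - window_s, side="left")
    idx = np.arange(len(x))
    out = (csum[idx + 1] - csum[start]) / (idx + 1 - start)
    return out


def classify_sudden_buildup(
    snapshot: Snapshot,
    smoothing_h: float = 4.0,
    horizon_h: float = 6.0,
    threshold_w: float = SUDDEN_RISE_W,
) -> bool:
    """Classify a pre-diagnosis power build-up as sudden or gradual.

    The pre-diagnosis power is smoothed with a trailing ``smoothing_h`` mean;
    the build-up is *sudden* when the smoothed power rises by strictly more
    than ``threshold_w`` (0.75 W) within any trailing ``horizon_h`` window.
    A multi-day gradual ramp gains far less than that in 6 h and stays
    gradual.
    """
    frame = snapshot.frame
    pre = frame[frame["timestamp"] <= snapshot.event_time]
    if pre.empty:
        raise InsufficientDataError("snapshot has no pre-diagnosis samples")
    t_s = pre["timestamp"].astype("int64").to_numpy() / 1e9
    smooth = _trailing_mean(t_s, pre["power_w"].to_numpy(float), smoothing_h * 3600.0)
    start = np.searchsorted(t_s, t_s - horizon_h * 3600.0, side="left")
    rise = smooth - np.array(
        [smooth[s : i + 1].min() for i, s in enumerate(start)]
    )
    return bool(rise.max() > threshold_w)


# ---------------------------------------------------------------------------
# LDH exponential model


@dataclass
class LdhModel:
    """Two-term exponential model of LDH versus days from diagnosis.

    ``y(t) = a·exp(b·t) + c·exp(d·t)`` with t in days (negative before
    diagnosis), a and c in U/L, b and d in 1/day.  Terms are canonically
    ordered with ``b ≥ d`` (fast term first).
    """

    a: float
    b: float
    c: float
    d: float
    rss: float
    covariance: np.ndarray
    n_points: int
    degenerate: bool = False

    def predict(self, times_days) -> np.ndarray:
        t = np.asarray(times_days, dtype=float)
        return self.a * np.exp(self.b * t) + self.c * np.exp(self.d * t)

    @property
    def params(self) -> tuple[float, float, float, float]:
        return self.a, self.b, self.c, self.d


def _two_exp(t, a, b, c, d):
    with np.errstate(over="ignore"):
        return a * np.exp(b * t) + c * np.exp(d * t)


#: Deterministic multi-start grid for the exponential rates, 1/day.
LDH_RATE_GRID = (0.1, 0.5, 1.0, 2.0)


def fit_ldh_model(
    times_days: Sequence[float],
    ldh: Sequence[float],
    t_max_days: float | None = None,
) -> LdhModel:
    """Fit the two-term exponential LDH model by nonlinear least squares.

    Initialisation is a deterministic multi-start: for every ordered pair of
    rates from :data:`LDH_RATE_GRID` (plus a zero slow rate), the amplitudes
    are solved by linear least squares at fixed rates, then all four
    parameters are refined; the start with the lowest residual sum of squares
    wins.  An explicit ``t_max_days`` restricts the fit domain (e.g. to
    samples earlier than half a day after diagnosis).

    Raises
    ------
    InsufficientDataError
        Fewer than 5 points after filtering.
    FitError
        No start converges.
    """
    t = np.asarray(times_days, dtype=float)
    y = np.asarray(ldh, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if t_max_days is not None:
        keep = t < t_max_days
        t, y = t[keep], y[keep]
    if len(t) < 5:
        raise InsufficientDataError("LDH fit requires at least 5 points")

    best = None
    rates = list(LDH_RATE_GRID)
    for b0, d0 in itertools.product(rates, rates + [0.0]):
        if b0 <= d0:
            continue
        design = np.column_stack([np.exp(b0 * t), np.exp(d0 * t)])
        try:
            (a0, c0), *_ = np.linalg.lstsq(design, y, rcond=None)
        except np.linalg.LinAlgError:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    _two_exp, t, y, p0=[a0, b0, c0, d0], maxfev=20000
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - _two_exp(t, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise FitError("no multi-start converged for the LDH model")

    rss, popt, pcov = best
    a, b, c, d = (float(v) for v in popt)
    if b < d:  # canonical order: fast term first
        a, b, c, d = c, d, a, b
        perm = [2, 3, 0, 1]
        pcov = pcov[np.ix_(perm, perm)]
    # the second term is unidentifiable when the rates nearly coincide or one
    # amplitude carries essentially no signal
    diag = np.diag(pcov)
    rate_sep = abs(b - d) / max(abs(b), abs(d), 1e-12)
    amp_ratio = min(abs(a), abs(c)) / max(abs(a), abs(c), 1e-12)
    degenerate = bool(
        (not np.all(np.isfinite(pcov)))
        or np.any(diag < 0)
        or rate_sep < 0.05
        or amp_ratio < 1e-4
    )
    return LdhModel(
        a=a, b=b, c=c, d=d, rss=rss, covariance=pcov,
        n_points=len(t), degenerate=degenerate,
    )


def control_band(control_ldh_values: Sequence[float]) -> tuple[float, float]:
    """95% confidence band for the control-group LDH mean (time-constant).

    Normal-approximation interval mean ± 1.96·SE with the sample standard
    deviation (ddof = 1).
    """
    values = np.asarray(control_ldh_values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("control band requires at least 2 values")
    mean = values.mean()
    se = values.std(ddof=1) / math.sqrt(values.size)
    return float(mean - 1.96 * se), float(mean + 1.96 * se)
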