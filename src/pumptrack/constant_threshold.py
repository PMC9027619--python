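"""Constant power-threshold detector — the clinical-practice comparator.

Clinical controllers alarm when pump power exceeds the patient's baseline by
a fixed number of watts (the manufacturer default is +2 W).  This module
implements that comparator: the baseline is the mean power over the first 1
or 5 days of a logfile, and every later sample is flagged when its power
exceeds baseline + δ.  Sweeping δ from 0.1 to 2.5 W in 0.1 W steps over a
cohort yields the detector's ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .io import ControlPeriod, PatientLog, SECONDS_PER_DAY, Snapshot
from .tracking import DetectionSeries

#: Canonical ROC threshold grid, W.
ROC_DELTAS = np.round(np.arange(0.1, 2.5 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class ConstantDetectorConfig:
    """Fixed-threshold detector parameters.

    ``baseline_days`` is canonically 1 or 5 (other positive values are
    accepted); ``delta_w`` is the alarm threshold above baseline, W.
    """

    baseline_days: float = 5.0
    delta_w: float = 1.0

    def __post_init__(self):
        if self.baseline_days <= 0:
            raise ValueError("baseline_days must be positive")
        if self.delta_w <= 0:
            raise ValueError("delta_w must be positive")


def _frame_of(data) -> pd.DataFrame:
    return data.frame if hasattr(data, "frame") else data


def compute_baseline(data, baseline_days: float) -> float:
    """Mean power over the first ``baseline_days`` of the log, W.

    The baseline window is ``t < t0 + baseline_days``; the log must span at
    least ``baseline_days`` so that at least one sample remains to evaluate.
    """
    frame = _frame_of(data)
    if frame.empty:
        raise InsufficientDataError("empty log")
    t = frame["timestamp"]
    span_days = (t.iloc[-1] - t.iloc[0]).total_seconds() / SECONDS_PER_DAY
    if span_days < baseline_days:
        raise InsufficientDataError(
            f"log spans {span_days:.1f} d < baseline of {baseline_days:g} d"
        )
    cut = t.iloc[0] + pd.Timedelta(days=baseline_days)
    base = frame.loc[t < cut, "power_w"]
    return float(base.mean())


def detect_constant(
    data: PatientLog | Snapshot | ControlPeriod, config: ConstantDetectorConfig
) -> DetectionSeries:
    """Flag every post-baseline sample whose power exceeds baseline + δ.

    Samples inside the baseline window are never flagged (a detector cannot
    alarm on the data that defines its own baseline).  The comparison is
    strict: power exactly at baseline + δ does not alarm.  The result reuses
    the detector-series container with the single threshold flag in the d1
    slot; the audit columns carry the constant baseline (``ma_long``) and the
    raw power (``ma_short``).
    """
    frame = _frame_of(data)
    baseline = compute_baseline(frame, config.baseline_days)
    t = frame["timestamp"].reset_index(drop=True)
    power = frame["power_w"].to_numpy(float)
    evaluable = (t >= t.iloc[0] + pd.Timedelta(days=config.baseline_days)).to_numpy()
    flags = evaluable & (power > baseline + config.delta_w)
    out = pd.DataFrame(
        {
            "timestamp": t,
            "d1": flags,
            "d2": False,
            "d3": False,
            "d4": False,
            "combined": flags,
            "ma_long": baseline,
            "ma_short": power,
            "integral": 0.0,
        }
    )
    return DetectionSeries(out)


@dataclass
class RocCurve:
    """ROC of the constant-threshold detector over a cohort.

    One row per threshold δ; sensitivity is snapshot-level (any pre-diagnosis
    flag), specificity is period-level (no flag at all).  Snapshots too short
    to support the baseline are excluded and counted in
    ``n_excluded_snapshots``.
    """

    deltas: np.ndarray
    sensitivity_pct: np.ndarray
    specificity_pct: np.ndarray
    baseline_days: float
    n_snapshots: int
    n_controls: int
    n_excluded_snapshots: int = 0

    def __post_init__(self):
        if np.any(np.diff(self.sensitivity_pct) > 1e-9):
            raise ValueError("ROC sensitivity must be non-increasing in delta")
        if np.any(np.diff(self.specificity_pct) < -1e-9):
            raise ValueError("ROC specificity must be non-decreasing in delta")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_w": self.deltas,
                "sensitivity_pct": self.sensitivity_pct,
                "specificity_pct": self.specificity_pct,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.1f")


def roc_sweep(
    pt_snapshots: Sequence[Snapshot],
    control_periods: Sequence[ControlPeriod],
    baseline_days: float = 5.0,
    deltas: np.ndarray = ROC_DELTAS,
) -> RocCurve:
    """Sweep the constant threshold over a cohort and build the ROC.

    For each snapshot the maximum post-baseline, pre-diagnosis power excess
    over baseline determines the largest δ still detecting it; likewise the
    maximum excess of each control period determines the smallest δ at which
    it stops false-alarming.  Sensitivity is therefore non-increasing and
    specificity non-decreasing in δ by construction.
    """
    if not len(pt_snapshots) or not len(control_periods):
        raise InsufficientDataError("roc_sweep requires nonempty cohorts")
    deltas = np.asarray(deltas, dtype=float)

    def max_excess(frame: pd.DataFrame, before=None) -> float | None:
        try:
            baseline = compute_baseline(frame, baseline_days)
        except InsufficientDataError:
            return None
        t = frame["timestamp"]
        mask = t >= t.iloc[0] + pd.Timedelta(days=baseline_days)
        if before is not None:
            mask &= t <= pd.Timestamp(before)
        if not mask.any():
            return None
        return float(frame.loc[mask, "power_w"].max() - baseline)

    snap_excess = [max_excess(s.frame, before=s.event_time) for s in pt_snapshots]
    n_excluded = sum(e is None for e in snap_excess)
    snap_excess = np.array([e for e in snap_excess if e is not None])
    if snap_excess.size == 0:
        raise InsufficientDataError("no evaluable snapshot in cohort")
    ctrl_excess = np.array(
        [max_excess(c.frame) for c in control_periods], dtype=float
    )

    sens = 100.0 * (snap_excess[:, None] > deltas[None, :]).mean(axis=0)
    spec = 100.0 * (ctrl_excess[:, None] <= deltas[None, :]).mean(axis=0)
    return RocCurve(
        deltas=deltas,
        sensitivity_pct=np.round(sens, 1),
        specificity_pct=np.round(spec, 1),
        baseline_days=baseline_days,
        n_snapshots=int(snap_excess.size),
        n_controls=len(control_periods),
        n_excluded_snapshots=int(n_excluded),
    )
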