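"""Seeded generator of synthetic pump controller logs and cohorts.

Real controller logfiles from LVAD patients are not public, so every stage
of the pipeline is exercised on synthetic telemetry that emulates the
statistical structure the detectors assume:

* 15-minute sampling cadence;
* a speed-dependent baseline power from the expected-power characteristic,
  with piecewise-constant operator speed changes;
* i.i.d. Gaussian sample noise (default σ = 0.1 W, small against the
  detector margins, as for a clinically quiet pump);
* an optional single-sinusoid 24-hour circadian modulation;
* thrombosis signatures injected as gradual ramps (linear or exponential)
  or sudden steps in the days before the diagnosis time.

All generators are deterministic per seed, and generated logs round-trip
through the logfile CSV dialect without loss (timestamps at second
resolution, power at 3 decimals).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SynthValidationError
from .evaluation import SUDDEN_RISE_W
from .expected_power import ExpectedPowerModel
from .io import ControlPeriod, PatientLog, Snapshot

#: Epoch used for synthetic timestamps.
T0 = pd.Timestamp("2020-01-01 00:00:00")

#: Pre-event rise (W) at which the surrogate annotation calls a power
#: signature visually "observable".  A synthetic stand-in for expert labels.
OBSERVABLE_RISE_W = 1.0


@dataclass(frozen=True)
class Ramp:
    """Gradual power build-up reaching ``height_w`` at the event time."""

    height_w: float
    onset_days_before_event: float
    shape: str = "linear"  # or "exponential"

    def __post_init__(self):
        if self.height_w <= 0:
            raise SynthValidationError("ramp height must be positive")
        if self.onset_days_before_event <= 0:
            raise SynthValidationError("ramp onset must precede the event")
        if self.shape not in ("linear", "exponential"):
            raise SynthValidationError(f"unknown ramp shape {self.shape!r}")


@dataclass(frozen=True)
class Step:
    """Sudden power step of ``height_w`` at ``days_before_event``."""

    height_w: float
    days_before_event: float

    def __post_init__(self):
        if self.height_w <= 0:
            raise SynthValidationError("step height must be positive")
        if self.days_before_event < 0:
            raise SynthValidationError("step must not start after the event")


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic telemetry stream.

    ``speed_rpm`` is either a constant or a piecewise-constant schedule of
    ``(start_day, rpm)`` pairs (first entry must start at day 0).  Defaults
    mirror a typical quiet control stream: 43.5 days at 2700 rpm with 0.1 W
    noise and no circadian modulation.
    """

    duration_days: float = 43.5
    speed_rpm: float | tuple = 2700.0
    noise_sd_w: float = 0.1
    circadian_amp_w: float = 0.0
    circadian_phase_h: float = 0.0
    anomaly: Ramp | Step | None = None
    seed: int = 0
    interval_s: float = 900.0
    start_time: pd.Timestamp = T0

    def __post_init__(self):
        if self.noise_sd_w < 0:
            raise SynthValidationError("noise_sd_w must be non-negative")
        if self.circadian_amp_w < 0:
            raise SynthValidationError("circadian_amp_w must be non-negative")
        if self.duration_days <= 0:
            raise SynthValidationError("duration_days must be positive")

    def speed_at(self, t_days: np.ndarray) -> np.ndarray:
        if np.isscalar(self.speed_rpm):
            return np.full_like(t_days, float(self.speed_rpm))
        sched = sorted(self.speed_rpm)
        starts = np.array([s for s, _ in sched])
        rpms = np.array([r for _, r in sched])
        idx = np.searchsorted(starts, t_days, side="right") - 1
        if np.any(idx < 0):
            raise SynthValidationError("speed schedule must start at day 0")
        return rpms[idx]


def _base_process(params: SynthParams, model: ExpectedPowerModel):
    """Time grid (days), speeds, and noiseless healthy power."""
    n = int(np.floor(params.duration_days * 86400.0 / params.interval_s)) + 1
    t_days = np.arange(n) * params.interval_s / 86400.0
    speeds = params.speed_at(t_days)
    clean = model.expected_power(speeds)
    if params.circadian_amp_w > 0:
        t_h = t_days * 24.0
        clean = clean + params.circadian_amp_w * np.sin(
            2 * np.pi * (t_h - params.circadian_phase_h) / 24.0
        )
    return t_days, speeds, clean


def _finish(params: SynthParams, t_days, speeds, clean) -> pd.DataFrame:
    rng = np.random.default_rng(params.seed)
    power = clean + rng.normal(0.0, params.noise_sd_w, size=len(clean))
    power = np.round(np.maximum(power, 0.0), 3)
    timestamps = params.start_time + pd.to_timedelta(
        np.round(t_days * 86400.0).astype("int64"), unit="s"
    )
    return pd.DataFrame(
        {
            "timestamp": timestamps,
            "speed_rpm": speeds,
            "power_w": power,
            "current_a": np.nan,
            "flow_lpm": np.nan,
        }
    )


def gen_control_log(
    params: SynthParams, model: ExpectedPowerModel, patient_id: str = "synth"
) -> PatientLog:
    """Generate an anomaly-free control telemetry stream."""
    if params.anomaly is not None:
        raise SynthValidationError("control log must have anomaly=None")
    t_days, speeds, clean = _base_process(params, model)
    frame = _finish(params, t_days, speeds, clean)
    return PatientLog(patient_id, frame, nominal_interval=params.interval_s)


def anomaly_profile(
    anomaly: Ramp | Step, t_days: np.ndarray, event_day: float
) -> np.ndarray:
    """Noiseless added-power profile of a thrombosis signature, W."""
    extra = np.zeros_like(t_days)
    if isinstance(anomaly, Step):
        extra[t_days >= event_day - anomaly.days_before_event] = anomaly.height_w
    elif isinstance(anomaly, Ramp):
        onset = event_day - anomaly.onset_days_before_event
        x = np.clip((t_days - onset) / anomaly.onset_days_before_event, 0.0, None)
        x_capped = np.minimum(x, 1.0)
        if anomaly.shape == "linear":
            rise = x_capped
        else:  # exponential: most of the rise concentrated near the event
            k = 5.0
            rise = np.expm1(k * x_capped) / np.expm1(k)
        extra = anomaly.height_w * rise
        extra[t_days > event_day] = anomaly.height_w  # plateau after diagnosis
    else:
        raise SynthValidationError(f"unknown anomaly {anomaly!r}")
    return extra


def _is_sudden(anomaly: Ramp | Step, horizon_h: float = 6.0) -> bool:
    """Ground-truth sudden label from the noiseless profile shape."""
    if isinstance(anomaly, Step):
        return anomaly.height_w > SUDDEN_RISE_W
    # max rise of the ramp profile over any horizon_h window
    grid = np.linspace(0.0, anomaly.onset_days_before_event, 2000)
    prof = anomaly_profile(anomaly, grid, anomaly.onset_days_before_event)
    h_days = horizon_h / 24.0
    start = np.searchsorted(grid, grid - h_days, side="left")
    rise = prof - prof[start]
    return bool(rise.max() > SUDDEN_RISE_W)


def gen_pt_snapshot(
    params: SynthParams,
    model: ExpectedPowerModel,
    patient_id: str = "synth-pt",
) -> tuple[Snapshot, dict]:
    """Generate a thrombosis snapshot (−14 d … +1 d) with ground truth.

    The stream covers 15 days with the diagnosis at day 14; the anomaly
    profile is added to the healthy control process.  Returns the snapshot
    and a truth record: anomaly descriptor, whether the signature is sudden
    (noiseless rise > 0.75 W within 6 h) and the surrogate annotation
    (observable iff the total pre-event rise reaches 1 W).
    """
    if params.anomaly is None:
        raise SynthValidationError("gen_pt_snapshot requires an anomaly")
    params = replace(params, duration_days=15.0)
    event_day = 14.0
    t_days, speeds, clean = _base_process(params, model)
    extra = anomaly_profile(params.anomaly, t_days, event_day)
    frame = _finish(params, t_days, speeds, clean + extra)
    event_time = params.start_time + pd.Timedelta(days=event_day)

    pre_rise = float(extra[t_days <= event_day].max())
    observable = pre_rise >= OBSERVABLE_RISE_W
    truth = {
        "patient_id": patient_id,
        "anomaly": type(params.anomaly).__name__.lower(),
        "height_w": params.anomaly.height_w,
        "sudden": _is_sudden(params.anomaly),
        "observable": observable,
        "event_time": event_time,
        "seed": params.seed,
    }
    snapshot = Snapshot(
        patient_id=patient_id,
        event_time=event_time,
        frame=frame,
        annotation_binary="observable" if observable else "not-observable",
    )
    return snapshot, truth


def gen_cohort(
    n_controls: int,
    n_pt: int,
    model: ExpectedPowerModel,
    control_params: SynthParams | None = None,
    pt_params: SynthParams | Sequence[SynthParams] | None = None,
    seed: int = 0,
) -> tuple[list[ControlPeriod], list[Snapshot], pd.DataFrame]:
    """Generate a labelled cohort of control periods and thrombosis snapshots.

    Per-patient seeds are derived from the master ``seed`` via a seed
    sequence, so the cohort is reproducible and order-independent across
    patients.  ``pt_params`` may be a single template (reused for every
    thrombosis patient) or one entry per patient.
    """
    if control_params is None:
        control_params = SynthParams()
    if pt_params is None:
        pt_params = SynthParams(
            anomaly=Ramp(height_w=2.0, onset_days_before_event=5.0)
        )
    if isinstance(pt_params, SynthParams):
        pt_params = [pt_params] * n_pt
    elif len(pt_params) != n_pt:
        raise SynthValidationError("need one pt_params per thrombosis patient")

    child_seeds = np.random.SeedSequence(seed).generate_state(n_controls + n_pt)
    child_seeds = [int(s) % (2**31) for s in child_seeds]

    controls: list[ControlPeriod] = []
    truth_rows: list[dict] = []
    for i in range(n_controls):
        pid = f"ctl-{i:03d}"
        log = gen_control_log(
            replace(control_params, seed=child_seeds[i]), model, patient_id=pid
        )
        controls.append(ControlPeriod(pid, log.frame))
        truth_rows.append(
            {
                "patient_id": pid,
                "anomaly": "none",
                "height_w": 0.0,
                "sudden": False,
                "observable": False,
                "event_time": pd.NaT,
                "seed": child_seeds[i],
            }
        )

    snapshots: list[Snapshot] = []
    for j in range(n_pt):
        pid = f"pt-{j:03d}"
        snap, truth = gen_pt_snapshot(
            replace(pt_params[j], seed=child_seeds[n_controls + j]),
            model,
            patient_id=pid,
        )
        snapshots.append(snap)
        truth_rows.append(truth)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id", "anomaly", "height_w", "sudden",
            "observable", "event_time", "seed",
        ],
    )
    return controls, snapshots, truth


def gen_ldh_series(
    a: float,
    b: float,
    c: float,
    d: float,
    noise_pct: float,
    times_days: Sequence[float],
    seed: int = 0,
) -> np.ndarray:
    """Noisy samples of the two-term exponential LDH curve.

    ``y(t)·(1 + ε)`` with ε ~ N(0, noise_pct) i.i.d. per point; times are in
    days relative to diagnosis and must lie within −14 … +0.5.
    """
    t = np.asarray(times_days, dtype=float)
    if np.any(t < -14.0) or np.any(t > 0.5):
        raise SynthValidationError("LDH times must lie within [-14, 0.5] days")
    y = a * np.exp(b * t) + c * np.exp(d * t)
    rng = np.random.default_rng(seed)
    return y * (1.0 + rng.normal(0.0, noise_pct, size=len(t)))
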