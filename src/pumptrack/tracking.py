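"""Self-adaptive four-detector pump-power tracking algorithm.

The algorithm watches a pump's power stream for deviations that may indicate
an evolving pump thrombosis.  It combines four independent detectors:

* **d1 — integrated transient deviation.**  Two trailing moving averages are
  maintained: a long one (the patient's historical baseline) and a short one
  (current operating power).  The rectified difference ``max(0, short − long)``
  is integrated over a trailing horizon; when the integral exceeds a threshold
  (in W·h) the detector fires.  This catches slow, gradual power build-ups
  that never breach an absolute level.
* **d2 — relative instantaneous excess.**  Instantaneous power exceeding a
  fixed ratio of the long-term moving average.
* **d3 — absolute instantaneous excess.**  Instantaneous power exceeding a
  fixed ratio of the pump's expected power at the current set speed.
* **d4 — post-initialisation guard.**  Same form as d3 with a tighter ratio,
  active only during the first 24 h after (re-)initialisation, when the
  moving averages have not yet adapted.

The tracker is *self-adaptive*: a manual change of the pump set speed larger
than ``speed_change_min`` rpm re-seeds both moving averages at the expected
power of the new speed, resets the integral and re-opens the d4 window, so
that an operator intervention never masquerades as a thrombosis signature.
Telemetry gaps longer than ``gap_reinit_h`` are treated like a pump restart.

Numeric thresholds are deliberately configuration: the packaged defaults are
chosen to give early warning on gradual multi-day ramps while staying silent
on circadian modulation and telemetry noise.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import OrderingError
from .expected_power import ExpectedPowerModel
from .io import ControlPeriod, LogSample, PatientLog, Snapshot

_H = 3600.0  # seconds per hour


@dataclass(frozen=True)
class TrackerConfig:
    """Tuning parameters of the four-detector tracker.

    Parameters
    ----------
    w_long_h, w_short_h : float
        Long- and short-term trailing moving-average windows, hours.
    int_window_h : float
        Trailing integration horizon of detector 1, hours.  A finite horizon
        lets transient deviations decay instead of accumulating forever.
    theta_int_wh : float
        Detector-1 alarm threshold on the integrated rectified difference,
        W·h.
    r_long_ma : float
        Detector-2 ratio: alarm when power > r_long_ma · long-term MA.
    r_expected : float
        Detector-3 ratio: alarm when power > r_expected · expected power.
    r_init : float
        Detector-4 ratio (tighter than r_expected), active ≤ init_horizon_h
        after initialisation.
    init_horizon_h : float
        Detector-4 active window after (re-)initialisation, hours.
    speed_change_min_rpm : float
        Set-speed delta that triggers baseline re-adaptation.
    persistence : int
        Consecutive exceedance samples required before detectors 2–4 flag;
        debounces single-sample telemetry spikes.
    gap_reinit_h : float
        Telemetry gap treated as a pump restart, hours.
    """

    w_long_h: float = 96.0
    w_short_h: float = 4.0
    int_window_h: float = 48.0
    theta_int_wh: float = 6.0
    r_long_ma: float = 1.25
    r_expected: float = 1.5
    r_init: float = 1.35
    init_horizon_h: float = 24.0
    speed_change_min_rpm: float = 60.0
    persistence: int = 2
    gap_reinit_h: float = 24.0

    def __post_init__(self):
        if not self.w_short_h < self.w_long_h:
            raise ValueError("w_short_h must be smaller than w_long_h")
        for name in ("r_long_ma", "r_expected", "r_init"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must exceed 1")
        if self.theta_int_wh <= 0:
            raise ValueError("theta_int_wh must be positive")
        if self.init_horizon_h <= 0:
            raise ValueError("init_horizon_h must be positive")
        if self.persistence < 1:
            raise ValueError("persistence must be at least 1")


@dataclass
class TrackerState:
    """Mutable running state of the tracker (one per telemetry stream)."""

    config: TrackerConfig
    ma_long: float
    ma_short: float
    integral: float = 0.0
    time_since_init_h: float = 0.0
    last_speed: float = 0.0
    init_time: float = 0.0  # epoch seconds
    last_time: float | None = None
    # trailing-window sample buffers: (epoch seconds, power W)
    buf_long: deque = field(default_factory=deque)
    buf_short: deque = field(default_factory=deque)
    sum_long: float = 0.0
    sum_short: float = 0.0
    # rectified short−long difference history for the d1 integral
    rect: deque = field(default_factory=deque)
    # consecutive exceedance counters for the persistence debounce
    run2: int = 0
    run3: int = 0
    run4: int = 0


def _epoch_s(t) -> float:
    return pd.Timestamp(t).value / 1e9


def _seed(state: TrackerState, t_s: float, level: float, speed: float) -> None:
    """(Re-)seed both moving averages at `level` and reset adaptive state."""
    state.buf_long = deque([(t_s, level)])
    state.buf_short = deque([(t_s, level)])
    state.sum_long = level
    state.sum_short = level
    state.ma_long = level
    state.ma_short = level
    state.rect = deque([(t_s, 0.0)])
    state.integral = 0.0
    state.init_time = t_s
    state.time_since_init_h = 0.0
    state.last_speed = speed
    state.run2 = state.run3 = state.run4 = 0


def init_state(
    config: TrackerConfig, first_sample: LogSample, model: ExpectedPowerModel
) -> TrackerState:
    """Initialise the tracker at pump start.

    Both moving averages are seeded at the expected power for the starting
    set speed; the d1 integral is zero and the d4 window opens.
    """
    level = model.expected_power(first_sample.speed)
    state = TrackerState(config=config, ma_long=level, ma_short=level)
    _seed(state, _epoch_s(first_sample.t), level, first_sample.speed)
    state.last_time = None
    return state


def readapt_on_speed_change(
    state: TrackerState, sample: LogSample, model: ExpectedPowerModel
) -> TrackerState:
    """Re-adapt the baseline after a manual set-speed change.

    Moving averages jump to the expected power of the new speed, the d1
    integral is cleared and the d4 post-initialisation window re-opens.
    """
    level = model.expected_power(sample.speed)
    _seed(state, _epoch_s(sample.t), level, sample.speed)
    return state


def _trim(buf: deque, cutoff: float) -> float:
    """Drop buffer entries strictly older than `cutoff`; return removed sum."""
    removed = 0.0
    while buf and buf[0][0] < cutoff:
        removed += buf.popleft()[1]
    return removed


def step(
    state: TrackerState,
    sample: LogSample,
    config: TrackerConfig | None = None,
    model: ExpectedPowerModel | None = None,
) -> tuple[TrackerState, tuple[bool, bool, bool, bool]]:
    """Advance the tracker by one sample; return the four detector flags.

    Samples must arrive in strictly increasing time order (the very first
    sample may coincide with the initialisation time).  The moving averages
    are unweighted means over samples inside their trailing windows; the d1
    integral is the trapezoidal integral of ``max(0, ma_short − ma_long)``
    over samples inside the trailing integration horizon.
    """
    if config is None:
        config = state.config
    if model is None:
        raise ValueError("step requires an expected-power model")

    t_s = _epoch_s(sample.t)
    if state.last_time is not None:
        if t_s <= state.last_time:
            raise OrderingError(
                f"sample at {sample.t} not after previous sample"
            )
        if t_s - state.last_time > config.gap_reinit_h * _H:
            # telemetry hole: treat like a pump restart
            _seed(state, t_s, model.expected_power(sample.speed), sample.speed)
    if abs(sample.speed - state.last_speed) >= config.speed_change_min_rpm:
        readapt_on_speed_change(state, sample, model)

    # moving averages over trailing windows
    state.buf_long.append((t_s, sample.power))
    state.sum_long += sample.power
    state.sum_long -= _trim(state.buf_long, t_s - config.w_long_h * _H)
    state.ma_long = state.sum_long / len(state.buf_long)

    state.buf_short.append((t_s, sample.power))
    state.sum_short += sample.power
    state.sum_short -= _trim(state.buf_short, t_s - config.w_short_h * _H)
    state.ma_short = state.sum_short / len(state.buf_short)

    # d1 integral: trapezoid of the rectified MA difference over the horizon
    r = max(0.0, state.ma_short - state.ma_long)
    if state.rect:
        t_prev, r_prev = state.rect[-1]
        state.integral += 0.5 * (r + r_prev) * (t_s - t_prev) / _H
    state.rect.append((t_s, r))
    cutoff = t_s - config.int_window_h * _H
    while len(state.rect) > 1 and state.rect[0][0] < cutoff:
        t0, r0 = state.rect.popleft()
        t1, r1 = state.rect[0]
        state.integral -= 0.5 * (r0 + r1) * (t1 - t0) / _H
    state.integral = max(0.0, state.integral)  # guard incremental round-off

    state.time_since_init_h = (t_s - state.init_time) / _H

    p_exp = model.expected_power(sample.speed)
    state.run2 = state.run2 + 1 if sample.power > config.r_long_ma * state.ma_long else 0
    state.run3 = state.run3 + 1 if sample.power > config.r_expected * p_exp else 0
    in_init = state.time_since_init_h <= config.init_horizon_h
    raw4 = in_init and sample.power > config.r_init * p_exp
    state.run4 = state.run4 + 1 if raw4 else 0

    d1 = state.integral >= config.theta_int_wh
    d2 = state.run2 >= config.persistence
    d3 = state.run3 >= config.persistence
    d4 = state.run4 >= config.persistence

    state.last_time = t_s
    state.last_speed = sample.speed
    return state, (d1, d2, d3, d4)


@dataclass
class DetectionSeries:
    """Per-sample detector flags with audit traces.

    ``combined`` is the OR of the four detector columns.  Audit columns carry
    the moving averages and the d1 integral so a flagged sample can be traced
    back to the responsible detector.
    """

    frame: pd.DataFrame  # timestamp,d1..d4,combined,ma_long,ma_short,integral

    def __post_init__(self):
        expected = self.frame[["d1", "d2", "d3", "d4"]].any(axis=1)
        if not (self.frame["combined"] == expected).all():
            raise ValueError("combined flag must equal d1 | d2 | d3 | d4")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def timestamps(self) -> pd.Series:
        return self.frame["timestamp"]

    @property
    def combined(self) -> np.ndarray:
        return self.frame["combined"].to_numpy(bool)

    @property
    def n_flagged(self) -> int:
        return int(self.frame["combined"].sum())

    def first_flag_time(self, before=None):
        """Earliest flagged timestamp (optionally restricted to t ≤ before)."""
        flagged = self.frame[self.frame["combined"]]
        if before is not None:
            flagged = flagged[flagged["timestamp"] <= pd.Timestamp(before)]
        if flagged.empty:
            return None
        return flagged["timestamp"].iloc[0]

    def flagged_duration_days(self, nominal_interval: float = 900.0) -> float:
        """Total flagged time, counting each flagged sample as one cadence."""
        return self.n_flagged * nominal_interval / 86400.0

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        for col in ("d1", "d2", "d3", "d4", "combined"):
            out[col] = out[col].astype(int)
        out.to_csv(path, index=False, float_format="%.6f")


def run_tracker(
    data: PatientLog | Snapshot | ControlPeriod,
    config: TrackerConfig | None = None,
    model: ExpectedPowerModel | None = None,
) -> DetectionSeries:
    """Fold the tracker over a full telemetry stream.

    Initialises at the first sample, steps through every sample (the first
    sample itself is evaluated — detector 4 covers the start-up window) and
    returns per-sample flags plus audit traces.
    """
    from .expected_power import DEFAULT_MODEL

    if config is None:
        config = TrackerConfig()
    if model is None:
        model = DEFAULT_MODEL
    frame = data.frame
    if frame.empty:
        raise ValueError("run_tracker requires a nonempty input")

    times = frame["timestamp"].to_numpy()
    speeds = frame["speed_rpm"].to_numpy(float)
    powers = frame["power_w"].to_numpy(float)
    # validate the whole speed range up front: one vector call instead of n
    model.expected_power(speeds)

    first = LogSample(t=frame["timestamp"].iloc[0], speed=speeds[0], power=powers[0])
    state = init_state(config, first, model)

    n = len(frame)
    flags = np.zeros((n, 4), dtype=bool)
    ma_long = np.empty(n)
    ma_short = np.empty(n)
    integral = np.empty(n)
    ts_series = frame["timestamp"].reset_index(drop=True)
    for i in range(n):
        sample = LogSample(t=ts_series.iloc[i], speed=speeds[i], power=powers[i])
        state, f = step(state, sample, config, model)
        flags[i] = f
        ma_long[i] = state.ma_long
        ma_short[i] = state.ma_short
        integral[i] = state.integral

    out = pd.DataFrame(
        {
            "timestamp": ts_series,
            "d1": flags[:, 0],
            "d2": flags[:, 1],
            "d3": flags[:, 2],
            "d4": flags[:, 3],
            "combined": flags.any(axis=1),
            "ma_long": ma_long,
            "ma_short": ma_short,
            "integral": integral,
        }
    )
    return DetectionSeries(out)


def config_from_mapping(section: dict) -> TrackerConfig:
    """Build a :class:`TrackerConfig` from a config-file mapping."""
    return replace(TrackerConfig(), **section)
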