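import numpy as np
import pandas as pd
import pytest

from pumptrack import DEFAULT_MODEL, PatientLog, TrackerConfig

T0 = pd.Timestamp("2020-01-01 00:00:00")


@pytest.fixture
def model():
    return DEFAULT_MODEL


@pytest.fixture
def config():
    return TrackerConfig()


def make_log(
    powers,
    speeds=2700.0,
    interval_s=900.0,
    patient_id="p1",
    start=T0,
    times_s=None,
):
    """Build a PatientLog from plain arrays (15-min cadence by default)."""
    powers = np.asarray(powers, dtype=float)
    n = len(powers)
    if times_s is None:
        times_s = np.arange(n) * interval_s
    timestamps = start + pd.to_timedelta(np.asarray(times_s), unit="s")
    speeds = np.broadcast_to(np.asarray(speeds, dtype=float), (n,))
    frame = pd.DataFrame(
        {
            "timestamp": timestamps,
            "speed_rpm": speeds,
            "power_w": powers,
            "current_a": np.nan,
            "flow_lpm": np.nan,
        }
    )
    return PatientLog(patient_id, frame, nominal_interval=interval_s)


def brute_force_ma(times_s, powers, window_s, seed_time_s, seed_value):
    """Oracle trailing mean: samples within [t−W, t] plus the init seed.

    The tracker seeds both averages with the expected power at the first
    sample's speed; the seed acts as a pseudo-sample at the init time until
    it ages out of the window.
    """
    out = np.empty(len(powers))
    for i, t in enumerate(times_s):
        vals = [powers[j] for j in range(i + 1) if times_s[j] >= t - window_s]
        if seed_time_s >= t - window_s:
            vals.append(seed_value)
        out[i] = np.mean(vals)
    return out


def brute_force_integral(times_s, ma_short, ma_long, window_s):
    """Oracle d1 integral: trapezoid of max(0, short−long) on the trailing
    window, over the sample grid."""
    rect = np.maximum(0.0, np.asarray(ma_short) - np.asarray(ma_long))
    out = np.empty(len(rect))
    t = np.asarray(times_s, dtype=float)
    for i in range(len(rect)):
        mask = (t >= t[i] - window_s) & (t <= t[i])
        out[i] = np.trapezoid(rect[mask], t[mask] / 3600.0)
    return out
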