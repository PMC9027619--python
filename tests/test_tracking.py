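"""Four-detector tracker: oracle equivalence, detectors, re-adaptation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import pumptrack as pt
from pumptrack.errors import OrderingError

from conftest import T0, brute_force_integral, brute_force_ma, make_log

E2700 = 4.4366  # expected power of the default curve at 2700 rpm


class TestInitState:
    def test_seeds_both_mas_with_expected_power(self, config, model):
        sample = pt.LogSample(t=T0, speed=2700.0, power=5.0)
        state = pt.init_state(config, sample, model)
        assert state.ma_long == pytest.approx(E2700, abs=1e-9)
        assert state.ma_short == pytest.approx(E2700, abs=1e-9)

    def test_integral_and_clock_start_at_zero(self, config, model):
        state = pt.init_state(config, pt.LogSample(t=T0, speed=3000.0, power=6.0), model)
        assert state.integral == 0.0
        assert state.time_since_init_h == 0.0


class TestStepDetectors:
    def test_d2_fires_on_relative_excess(self, model):
        # flat at expected power, then a sustained jump beyond 1.25x long MA
        cfg = pt.TrackerConfig(persistence=1)
        powers = np.full(200, E2700)
        powers[100:] = 6.2  # 1.25 * ma_long ~ 5.55 W
        series = pt.run_tracker(make_log(powers), cfg, model)
        assert series.frame["d2"].iloc[100]
        assert not series.frame["d2"].iloc[:100].any()

    def test_persistence_debounces_single_spike(self, model):
        cfg = pt.TrackerConfig(persistence=2)
        powers = np.full(200, E2700)
        powers[100] = 8.0  # lone telemetry spike
        series = pt.run_tracker(make_log(powers), cfg, model)
        assert not series.frame[["d2", "d3", "d4"]].to_numpy().any()
        powers[101] = 8.0  # sustained for 2 samples -> fires
        series = pt.run_tracker(make_log(powers), cfg, model)
        assert series.frame["d2"].iloc[101] and series.frame["d3"].iloc[101]

    def test_flat_log_at_expected_power_never_flags(self, config, model):
        series = pt.run_tracker(make_log(np.full(500, E2700)), config, model)
        assert series.n_flagged == 0

    def test_out_of_order_sample_raises(self, config, model):
        state = pt.init_state(config, pt.LogSample(t=T0, speed=2700.0, power=4.4), model)
        state, _ = pt.step(state, pt.LogSample(t=T0, speed=2700.0, power=4.4), config, model)
        with pytest.raises(OrderingError):
            pt.step(state, pt.LogSample(t=T0, speed=2700.0, power=4.4), config, model)

    def test_single_sample_log(self, config, model):
        series = pt.run_tracker(make_log([E2700]), config, model)
        assert len(series) == 1
        assert not series.combined[0]

    def test_d4_active_only_after_init(self, model):
        # power above r_init x expected but below r_expected x expected:
        # only the post-init detector can fire, and only within 24 h
        cfg = pt.TrackerConfig(persistence=1, r_init=1.05, r_long_ma=2.0,
                               r_expected=1.5, theta_int_wh=1e9)
        powers = np.full(200, 1.1 * E2700)
        series = pt.run_tracker(make_log(powers), cfg, model)
        within = series.frame["timestamp"] <= T0 + pd.Timedelta(hours=24)
        assert series.frame.loc[within, "d4"].all()
        assert not series.frame.loc[~within, "d4"].any()
        assert not series.frame["d3"].any()


class TestD1Integral:
    def test_first_fire_matches_brute_force_oracle(self, model):
        """Sustained short/long MA separation integrates to the W·h threshold.

        With a ~0.5 W plateau in the MA difference and theta = 6 W·h the
        alarm must arrive roughly 12 h after the plateau forms; the exact
        index is pinned by the brute-force oracle.
        """
        cfg = pt.TrackerConfig(w_long_h=400.0, w_short_h=1.0, theta_int_wh=6.0,
                               int_window_h=48.0, r_long_ma=10.0, r_expected=10.0,
                               r_init=9.0)
        n_pre = 10 * 96  # 10 flat days pin the long-term MA near expected
        powers = np.concatenate([np.full(n_pre, E2700), np.full(200, E2700 + 0.5)])
        log = make_log(powers)
        series = pt.run_tracker(log, cfg, model)

        t_s = np.arange(len(powers)) * 900.0
        mal = brute_force_ma(t_s, powers, cfg.w_long_h * 3600, 0.0, E2700)
        mas = brute_force_ma(t_s, powers, cfg.w_short_h * 3600, 0.0, E2700)
        integral = brute_force_integral(t_s, mas, mal, cfg.int_window_h * 3600)
        oracle_first = np.flatnonzero(integral >= cfg.theta_int_wh)[0]
        tracker_first = np.flatnonzero(series.frame["d1"].to_numpy())[0]
        assert tracker_first == oracle_first
        hours_after_step = (oracle_first - n_pre) * 0.25
        assert 12.0 <= hours_after_step <= 14.0  # ~0.5 W x 12 h = 6 W·h

    def test_ma_and_integral_traces_match_oracle_on_random_logs(self, config, model):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = 192  # 2 days
            powers = np.round(E2700 + rng.normal(0, 0.3, n).cumsum() * 0.05
                              + rng.normal(0, 0.1, n), 3)
            powers = np.maximum(powers, 0.1)
            log = make_log(powers)
            series = pt.run_tracker(log, config, model)
            t_s = np.arange(n) * 900.0
            mal = brute_force_ma(t_s, powers, config.w_long_h * 3600, 0.0, E2700)
            mas = brute_force_ma(t_s, powers, config.w_short_h * 3600, 0.0, E2700)
            integ = brute_force_integral(t_s, mas, mal, config.int_window_h * 3600)
            np.testing.assert_allclose(series.frame["ma_long"], mal, atol=1e-9)
            np.testing.assert_allclose(series.frame["ma_short"], mas, atol=1e-9)
            np.testing.assert_allclose(series.frame["integral"], integ, atol=1e-9)

    def test_shift_invariance_of_d1(self, config, model):
        rng = np.random.default_rng(7)
        powers = E2700 + np.abs(rng.normal(0, 0.4, 300)).cumsum() * 0.01
        base = pt.run_tracker(make_log(powers), config, model)
        c = 1.5
        coeffs = list(model.coeffs)
        coeffs[0] += c
        shifted_model = pt.ExpectedPowerModel(tuple(coeffs), model.valid_speed_range)
        shifted = pt.run_tracker(make_log(powers + c), config, shifted_model)
        np.testing.assert_array_equal(
            base.frame["d1"].to_numpy(), shifted.frame["d1"].to_numpy()
        )


class TestSpeedReadaptation:
    def test_baseline_jumps_to_new_expected_power(self, config, model):
        state = pt.init_state(config, pt.LogSample(t=T0, speed=2700.0, power=4.4), model)
        sample = pt.LogSample(t=T0 + pd.Timedelta("15min"), speed=3000.0, power=5.9)
        pt.readapt_on_speed_change(state, sample, model)
        assert state.ma_long == pytest.approx(model.expected_power(3000.0))
        assert state.integral == 0.0
        assert state.time_since_init_h == 0.0

    def test_small_jitter_does_not_readapt(self, model):
        cfg = pt.TrackerConfig(speed_change_min_rpm=60.0, persistence=1)
        speeds = np.full(100, 2700.0)
        speeds[50:] = 2710.0  # below the 60 rpm re-adaptation threshold
        powers = np.full(100, E2700)
        series = pt.run_tracker(make_log(powers, speeds=speeds), cfg, model)
        # MA continuity: no jump to expected power of the new speed
        assert series.frame["ma_long"].iloc[51] == pytest.approx(
            series.frame["ma_long"].iloc[49], abs=0.01
        )

    def test_no_flags_after_readapt_at_new_expected_level(self, config, model):
        speeds = np.concatenate([np.full(300, 2700.0), np.full(300, 3000.0)])
        powers = np.concatenate(
            [np.full(300, model.expected_power(2700.0)),
             np.full(300, model.expected_power(3000.0))]
        )
        series = pt.run_tracker(make_log(powers, speeds=speeds), config, model)
        assert series.n_flagged == 0

    def test_gap_longer_than_24h_reinitializes(self, config, model):
        times = np.concatenate([np.arange(100) * 900.0,
                                60 * 3600 + np.arange(100) * 900.0])  # ~35 h hole
        powers = np.full(200, E2700 + 1.0)  # constant offset from expected
        series = pt.run_tracker(make_log(powers, times_s=times), config, model)
        # after the hole the tracker restarts: integral back to zero
        assert series.frame["integral"].iloc[100] == pytest.approx(0.0, abs=1e-12)
        assert series.frame["integral"].iloc[99] > 0


class TestMonotonicity:
    def test_relaxing_thresholds_never_removes_flags(self, model):
        rng = np.random.default_rng(3)
        ramp = np.linspace(0, 1.6, 400)
        powers = np.round(E2700 + ramp + rng.normal(0, 0.1, 400), 3)
        log = make_log(np.maximum(powers, 0.1))
        tight = pt.TrackerConfig()
        loose = dataclasses.replace(
            tight, theta_int_wh=3.0, r_long_ma=1.1, r_expected=1.2, r_init=1.15
        )
        flags_tight = pt.run_tracker(log, tight, model).combined
        flags_loose = pt.run_tracker(log, loose, model).combined
        assert np.all(flags_loose | ~flags_tight)  # tight set nested in loose


class TestEndToEnd:
    def test_quiet_control_log_has_no_flags(self, config, model):
        params = pt.SynthParams(duration_days=43.0, noise_sd_w=0.1, seed=21)
        log = pt.gen_control_log(params, model)
        assert pt.run_tracker(log, config, model).n_flagged == 0

    def test_gradual_ramp_flagged_before_event(self, config, model):
        params = pt.SynthParams(
            anomaly=pt.Ramp(height_w=1.5, onset_days_before_event=5.0), seed=22
        )
        snap, _ = pt.gen_pt_snapshot(params, model)
        series = pt.run_tracker(snap, config, model)
        first = series.first_flag_time()
        assert first is not None and first < snap.event_time

    def test_circadian_control_stays_silent(self, config, model):
        for seed in range(5):
            params = pt.SynthParams(
                duration_days=14.0, circadian_amp_w=0.3, noise_sd_w=0.1, seed=seed
            )
            log = pt.gen_control_log(params, model)
            assert pt.run_tracker(log, config, model).n_flagged == 0

    def test_detection_series_csv_roundtrip_columns(self, config, model, tmp_path):
        log = pt.gen_control_log(pt.SynthParams(duration_days=2, seed=0), model)
        series = pt.run_tracker(log, config, model)
        path = tmp_path / "det.csv"
        series.to_csv(path)
        back = pd.read_csv(path)
        assert list(back.columns) == [
            "timestamp", "d1", "d2", "d3", "d4", "combined",
            "ma_long", "ma_short", "integral",
        ]
        assert len(back) == len(series)
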