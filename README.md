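# pumptrack

Adaptive pump-power tracking for early warning of pump thrombosis in
centrifugal left ventricular assist devices (LVADs).

An implanted centrifugal blood pump logs its set speed, power consumption,
current and estimated flow on the controller every 15 minutes.  Clot
formation on the impeller (intra-pump thrombosis, PT) increases the power the
pump draws, often days before the diagnosis is made from hemolysis markers
and clinical findings.  Clinically available alarms compare power to a fixed
threshold above a baseline (typically +2 W), which is both insensitive to
slow build-ups and blind to patient-specific operating levels.  `pumptrack`
implements an adaptive alternative and everything needed to validate it:

* **Four-detector power tracking** (`pumptrack.tracking`).  A long-term
  trailing moving average `MA_long` estimates the patient's baseline power; a
  short-term average `MA_short` tracks current operation.  Detector 1
  integrates the rectified difference `max(0, MA_short − MA_long)` over a
  trailing horizon and alarms when the integral exceeds a threshold θ (W·h)
  — sensitive to gradual multi-day ramps.  Detectors 2–4 alarm on
  instantaneous power exceeding `r · MA_long`, `r · P_exp(ω)` and (during the
  first 24 h after initialisation) a tighter `r · P_exp(ω)`, where
  `P_exp(ω)` is the pump's expected power at set speed ω.  A manual speed
  change re-seeds the baseline at `P_exp(ω_new)` so operator interventions do
  not alarm.
* **Constant-threshold comparator and ROC** (`pumptrack.constant_threshold`).
  Power compared to a 1- or 5-day baseline plus δ, with δ swept 0.1–2.5 W in
  0.1 W steps.
* **Evaluation harness** (`pumptrack.evaluation`).  Snapshot-level
  sensitivity, period-level specificity, accuracy, signed early-warning
  times, false positives per patient-year (365.25 d), a circadian-rhythm test
  (dominant FFT period within 24 h ± 30 min), sudden-vs-gradual build-up
  classification (> 0.75 W rise of smoothed power within 6 h) and a two-term
  exponential model of the hemolysis marker LDH,
  `y(t) = a·e^{b·t} + c·e^{d·t}`.
* **Synthetic telemetry generator** (`pumptrack.synthgen`).  Seeded 15-minute
  logs with speed-dependent baseline, Gaussian noise, optional 24-h circadian
  modulation, operator speed steps, and injected thrombosis signatures (steps
  and linear/exponential ramps) with ground-truth labels — real controller
  logfiles from patients are not publicly available.

The package is aimed at medical-device signal-processing researchers who
want to study, stress-test or extend power-based thrombosis alarms.

## Worked example

```python
import pumptrack as pt

model = pt.DEFAULT_MODEL            # cubic speed->power curve, config not code
config = pt.TrackerConfig()         # documented default detector thresholds

# 3 quiet control streams + 2 thrombosis snapshots with a +2 W 5-day ramp
controls, snapshots, truth = pt.gen_cohort(
    n_controls=3, n_pt=2, model=model,
    control_params=pt.SynthParams(duration_days=20.0),
    pt_params=pt.SynthParams(anomaly=pt.Ramp(height_w=2.0, onset_days_before_event=5.0)),
    seed=1,
)

snap_runs = [(pt.run_tracker(s, config, model), s.event_time) for s in snapshots]
ctrl_runs = [(c.patient_id, pt.run_tracker(c, config, model), c.duration_days)
             for c in controls]
report = pt.evaluate_cohort(snap_runs, ctrl_runs)

print(f"sensitivity:   {report.sensitivity_pct}%")
print(f"specificity:   {report.specificity_pct}%")
print(f"early warnings (days): {report.early_warnings_days}")
print(f"median early warning:  {report.median_early_warning_days:.2f} days")
print(f"control monitoring:    {report.patient_years_control:.3f} patient-years")
```

prints

```
sensitivity:   100.0%
specificity:   100.0%
early warnings (days): [-3.7708333333333335, -3.7604166666666665]
median early warning:  -3.77 days
control monitoring:    0.164 patient-years
```

Both injected ramps are caught roughly 3.8 days before the diagnosis time
(negative = alarm precedes diagnosis) and none of the flat control streams
raises a false alarm.  The same pipeline is available from the shell:

```sh
pumptrack simulate --config run.yaml --seed 1 --out-dir cohort
pumptrack evaluate --config run.yaml --out-dir results   # report.json
pumptrack roc      --config run.yaml --out-dir results   # 25-point ROC CSV
```

where `run.yaml` holds `tracker`, `constant`, `expected_power`, `simulate`
and `paths` sections (see `pumptrack.cli`).

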