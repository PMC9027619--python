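# Methods

## Problem setting

A continuous-flow centrifugal LVAD operates at a clinician-set impeller
speed ω (rpm) and draws electrical power P(t) (W), logged by the controller
every 15 minutes.  Thrombus forming on the impeller increases the hydraulic
and frictional load and with it the power uptake — sometimes as a sudden
step, sometimes as a gradual multi-day ramp.  The package detects such
abnormal power uptake against a patient-specific baseline and evaluates the
detector the way alarm-validation studies do: snapshot-level sensitivity on
diagnosed thrombosis windows, period-level specificity and false-alarm
burden on event-free control periods.

## Data model and windowing

A patient's telemetry is one strictly time-ordered stream assembled from
several downloaded logfiles (`aggregate_logs`); exact duplicates are
collapsed, and duplicates that *conflict* in value raise an error by default
(`keep_first=True` downgrades to a warning).  The deduplication rule only
defines the duplicate case, so conflicts fail loudly rather than silently
picking a value.

* **Thrombosis snapshot**: the closed window [diagnosis − 14 d, diagnosis
  + 1 d].  A sample exactly at the diagnosis time counts as pre-diagnosis in
  all detection accounting.
* **Repeat events** on one patient are only analysed if strictly more than
  14 days after the previously kept event.
* **Control periods** are supplied as pre-screened eligibility intervals
  (normal laboratory values, no admission, no hypertension — screened
  upstream, consumed as data).  Within an interval the log is split wherever
  the telemetry gap exceeds 4 × the nominal cadence (1 h) — the log is no
  longer "continuous monitoring" across a day-long hole — and segments
  shorter than 14 days are excluded.
* **Patient-year**: fixed at 365.25 days everywhere.

## Expected-power characteristic

`P_exp(ω)` is a cubic polynomial in rpm with configurable coefficients and a
validity range; device-specific coefficients are manufacturer data, so they
are configuration, not code.  The packaged synthetic default
`P_exp(ω) = 0.5 + 2.0·10⁻¹⁰ ω³` gives ≈ 3.5–7.5 W over 2400–3200 rpm, the
clinically typical speed band.  An optional symmetric band half-width is
supported for uses that need power *ranges* rather than a single curve.
Normalised power (P / P_exp) makes patients at different set speeds
comparable.

## The four-detector tracker

State: trailing buffers for a long-term moving average `MA_long` (baseline)
and a short-term moving average `MA_short` (current operation), a running
integral, and the time since (re-)initialisation.  Both averages are
*unweighted means over samples inside the trailing window*; exponential
smoothing was rejected so that a brute-force oracle can reproduce the traces
exactly.  At initialisation (pump start, telemetry hole > 24 h, or a set
speed change ≥ 60 rpm) both averages are seeded with `P_exp(ω)`; the seed
acts as a pseudo-sample at the initialisation time and ages out of the
windows naturally.

Per sample, with expected power `P_exp(ω)`:

| detector | condition | default |
|---|---|---|
| d1 | trailing trapezoidal integral of `max(0, MA_short − MA_long)` ≥ θ | θ = 6 W·h over a 48 h horizon |
| d2 | `P > r_MA · MA_long`, sustained | r_MA = 1.25 |
| d3 | `P > r_exp · P_exp(ω)`, sustained | r_exp = 1.5 |
| d4 | within 24 h of initialisation and `P > r_init · P_exp(ω)`, sustained | r_init = 1.35 |

Windows default to 96 h (long) and 4 h (short).  "Sustained" means the raw
condition holds for `persistence = 2` consecutive samples; this debounces
single-sample telemetry spikes.  The combined alarm is the OR of the four
flags, evaluated per sample and non-latching (no manual reset semantics).
The d1 integral is *rectified* (negative differences do not pay down the
integral) and uses a finite trailing horizon so transient deviations decay
instead of accumulating indefinitely.  Integration is trapezoidal on the
(possibly irregular) timestamp grid, maintained incrementally with a
non-negativity guard against incremental round-off.

The numeric thresholds of the original controller algorithm were trained on
proprietary data and are not published; the defaults above are this
package's own calibration, chosen so that the detector gives early warning
on gradual multi-day ramps while staying silent on a 0.3 W 24-h circadian
modulation with 0.1 W sample noise (the d1 integral of that modulation
peaks near 4.8 W·h, safely under θ = 6 W·h).  Every threshold is
configuration.

Monotonicity holds by construction: lowering any of θ, r_MA, r_exp, r_init
can only add flagged samples.

## Constant-threshold comparator

Baseline B = mean power over the first 1 or 5 days of the stream
(`t < t₀ + baseline_days`); a later sample alarms iff `P > B + δ` (strict).
Baseline-window samples are never flagged — a detector cannot alarm on the
data that defines its own baseline.  Snapshots too short to support the
baseline are excluded from the ROC and counted.  The sweep uses
δ = 0.1 … 2.5 W in 0.1 W steps (25 points); sensitivity/specificity per δ
follow the cohort definitions below, which makes the ROC coordinates
monotone in δ by construction.  The clinical "+2 W above baseline" alarm is
simply δ = 2.0 with this detector.

## Evaluation definitions

* **Sensitivity** = snapshots with ≥ 1 combined alarm at t ≤ diagnosis,
  over all snapshots (percent, one decimal — matching the house reporting
  style throughout).
* **Specificity** = control periods with *no* alarm at all, over all
  periods.  Any flagged sample makes a period a false positive regardless
  of flagged duration; flagged durations are reported alongside (number of
  flagged samples × cadence).
* **Accuracy** = (TP + TN) / (snapshots + periods).  No standard source
  defines this pooling for the alarm setting; the conventional confusion
  formula is used and documented here because published accuracies cannot
  be re-derived without the unpublished control-period count.
* **Early warning** = (first alarm − diagnosis) in days; negative means the
  alarm preceded the diagnosis.  Summaries report the median.
* **False-positive interval** = control patient-years / false-positive
  periods; infinite (reported as none observed) when there is none.

## Circadian analysis

Daily physiological rhythm modulates pump power with a ≈ 24 h period.  The
test removes the mean and a linear trend, applies a Hann window (both
suppress leakage from slow thrombosis ramps into low frequencies), computes
the FFT power spectrum, and takes the dominant period as the reciprocal of
the peak frequency among periods no longer than half the record.  A record
is circadian when the dominant period falls within 24 h ± 30 min.  On a
14-day record the frequency resolution is 1/336 h⁻¹, so an 8/12/24/36-h
sinusoid is recovered within one bin; under white noise the 23.5–24.5 h
band covers less than one bin in frequency, so false circadian calls are
rare.  At least 2 days of data are required.

## Sudden vs. gradual build-up

The pre-diagnosis power is smoothed with the tracker's short window (4 h
trailing mean); a build-up is *sudden* when the smoothed power rises by
strictly more than 0.75 W within any trailing 6 h window, else gradual.
The 0.75 W magnitude is the established discriminator; the 6-h horizon and
the smoothing are this package's operationalisation (a step must be fast on
the scale of hours to be "sudden"; 6 h also makes the boundary rate an
interpretable 0.125 W/h).  A +1.5 W ramp spread over 5 days gains only
0.075 W per 6 h and is therefore gradual; a +1 W step is sudden.

## LDH exponential model

Intra-pump thrombosis shears red cells, and the hemolysis marker lactate
dehydrogenase (LDH, U/L) rises roughly exponentially in the final days
before diagnosis.  The model `y(t) = a·e^{bt} + c·e^{dt}` (t in days
relative to diagnosis, negative before) is fitted by nonlinear least
squares with a deterministic multi-start: for every ordered rate pair from
{0.1, 0.5, 1.0, 2.0} d⁻¹ (slow rate may also be 0) the amplitudes are
solved linearly at fixed rates, then all four parameters are refined; the
lowest-RSS start wins.  Terms are canonically ordered fast-first (b ≥ d),
resolving the label-swap symmetry.  Fits are flagged *degenerate* when the
rates nearly coincide (relative separation < 5%), one amplitude is
negligible (< 10⁻⁴ of the other), or the covariance is unusable — in all
three cases the second term is unidentifiable.  At least 5 points are
required; an explicit `t_max_days` filter restricts the fit domain (e.g. to
samples earlier than +0.5 d) rather than hard-coding a display convention.
The control-group reference is a time-constant normal-approximation band,
mean ± 1.96 · SE.

## Synthetic data

The generator emulates exactly the structure the detectors assume: a
15-minute grid, power = `P_exp(ω)` + optional single-sinusoid 24-h
modulation + i.i.d. Gaussian noise, piecewise-constant speed schedules, and
injected signatures (steps; linear ramps; exponential ramps concentrating
the rise near the event).  Defaults are the study conditions used
throughout: 43.5-day control periods (the typical control-segment length),
2700 rpm (a typical clinical set speed), σ = 0.1 W noise.  Ground-truth
labels come from the noiseless profile: *sudden* iff the profile rises more
than 0.75 W within 6 h; the surrogate annotation calls a signature
*observable* iff the total pre-event rise reaches 1 W.  That surrogate is a
synthetic stand-in for expert annotation chosen to align with the best
constant threshold (+1 W), not a claim about expert behaviour.  Power is
rounded to 3 decimals and timestamps to seconds so logs round-trip through
the CSV dialect losslessly.  Per-patient seeds derive from the master seed
via a seed sequence, making cohorts reproducible and order-independent.

What the generator does **not** emulate: suction events, arrhythmia
artifacts, hemodynamic instability, autocorrelated or heavy-tailed noise,
circadian harmonics, or realistic current/flow channels.  Passing the
synthetic suites therefore demonstrates algorithmic correctness and the
intended qualitative behaviour (early warning on ramps, silence on
circadian controls), not clinical performance; the published clinical
numbers were obtained on non-public patient data and are reproduced here
only at the level of metric arithmetic on the printed counts.

## Problem sizes and numerical notes

The test and acceptance runs use cohorts of 20 control periods (43.5 d
each) + 10 snapshots, 50–100 seeded replicates for oracle-equivalence,
circadian and LDH-recovery suites, and 2-day logs for the O(n²) brute-force
oracles — sizes at which every oracle is exact and the full pipeline runs
in seconds.  Other conventions: window membership is closed at both ends of
each trailing window; ROC deltas are rounded to avoid floating-grid
artifacts; percentages are rounded to one decimal at the reporting
boundary only.

## Known limitations

* Detector thresholds are a synthetic calibration, not the proprietary
  trained values; absolute performance numbers on real data will differ.
* The d1 integral's horizon and rectification, alarm non-latching, the
  sudden-build-up horizon, and the accuracy pooling are documented design
  choices where the field's conventions are not fixed.
* The constant-threshold ROC treats each snapshot/period as one unit;
  within-patient correlation of repeat events is not modelled.
* `MA` traces are means over available samples; irregular sampling is
  handled, but systematic missingness patterns are not modelled by the
  generator.
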