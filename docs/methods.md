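# Methods

This note records the models, conventions, and design decisions behind
`wearvalid`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Study design being analyzed (and emulated)

The pipeline targets a device-validation design in which each participant
wears several candidate sensors and reference devices simultaneously while
performing a standardized protocol: 17 tasks, 57 minutes of task time,
grouped into six activity clusters — resting, walking, metronome breathing
(paced at 6, 15, 20, and 24 brpm), household chores, stationary cycling (to
a heart rate of at least 120 bpm), and recovery. Tasks are separated by
transition periods that never enter any analysis. Four vital signs are
covered: HR (bpm), RR (brpm), SpO₂ (%), and skin temperature (°C), yielding
12 wearable-reference combinations across four wearable placements (right
arm, left arm, chest, wrist) and two reference types.

The exact per-task durations of such protocols are typically published only
as supplements; the packaged default schedule is therefore a stand-in with
task durations of 2–10 minutes summing to 57 minutes (resting 13, walking
9, breathing 4 × 2, chores 9, cycling 10, recovery 8). It is defined in
`wearvalid.protocol` and exported as an editable CSV by `wearvalid
simulate`, so any run can substitute a different schedule file.

## 2. Synthetic cohort generator

### Ground truth

Per vital sign, a dense trajectory (1 value/second inside task windows,
window ends inclusive) is generated from cluster-specific trends:

* `constant(level, sd)` — level plus variability;
* `ramp(start, target, sd)` — linear over the cluster's total task time;
  the deterministic component is monotone and reaches the target within the
  cluster (the cycling HR default ramps 85 → 126 bpm so the 120 bpm
  criterion is met);
* `metronome(sequence)` — the cluster's tasks take the configured rates
  exactly, one per task, with variability suppressed, so paced respiratory
  rate is reproduced without error.

Variability is a stationary AR(1) Gaussian process (lag-1 correlation 0.95
at 1 s steps) scaled to the trend's sd and clipped to physiological ranges
(HR 30–220 bpm, RR 4–60 brpm, SpO₂ 70–100%, temperature 25–40 °C). AR(1)
was chosen over white noise because vital signs drift smoothly at the
seconds scale; the correlation value is a fixed modeling constant, not a
tuning knob.

### Device observation model

A device stores samples at t = start + k·period, k = 1..⌊duration/period⌋,
inside each task window — no sample at the window start, and ⌊D/p⌋ expected
samples per window, which reproduces the expected-count arithmetic of the
emulated protocol (57 min at 4 s → 855 samples/participant, 17,100 for 20
participants; at 5 s → 684 and 13,680). A stored value is

    truth(t) + bias[cluster] + subject_offset + AR1(σ[cluster], ρ) ,

quantized to the device resolution (e.g. 0.5 °C for the temperature
loggers, 1 bpm for heart-rate channels). Two features deserve comment:

* **subject_offset** ~ N(0, `subject_bias_sd`), drawn once per
  (participant, device, vital): per-subject calibration error. Without it,
  paired differences would have no between-subject variance component and
  the repeated-measures Bland-Altman machinery would have nothing to
  estimate.
* **noise_rho** — lag-1 autocorrelation of observation noise across
  consecutive stored samples. Wearable error is strongly autocorrelated in
  practice (posture, perfusion, sensor contact), which is why minute-median
  aggregation narrows limits of agreement only modestly; with white noise
  the minute-level LoA would collapse by ≈ 1/√(samples per minute) and
  misrepresent that behavior. Defaults: 0.85 for PPG/ECG channels, 0.6
  for temperature and reference channels.

Dropout epochs are Poisson per task (cluster-specific rate, epochs/min)
with log-normal durations; each epoch deletes all stored samples in
[start, start + duration). Log-normal durations give the heavy right tail
observed in practice (most epochs a few seconds; occasional multi-minute
outages for optical channels during movement).

Default bias/noise/dropout values per device and cluster (in
`wearvalid.protocol`) are chosen so that the synthetic cohort reproduces
the magnitudes reported for this class of devices: near-complete
availability for chest-patch and arm HR/temperature channels, ≈30–35%
missing wrist HR dominated by epochs ≤ 10 s, heavy SpO₂ dropout during
walking/chores, cycling-cluster HR biases of ≈ 0 (chest patch), −4 to −5
(arm), and −11.4 bpm (wrist) with correspondingly wide LoA, and temperature
offsets of +0.5 °C (chest patch vs co-located logger) and +2.7/+2.9 °C
(arm). Site differences in skin temperature (arm vs chest) are expressed as
additive device biases against a single shared truth, so only differences
between co-located devices are physically meaningful.

Determinism: the master seed feeds a `numpy.random.SeedSequence`; each
participant spawns a child, and within a participant one grandchild per
vital-sign truth and per (device, vital) channel in fixed sorted order.
Identical configuration and seed give byte-identical cohorts.

### What the generator does not emulate

No cardiorespiratory mechanics, no raw ECG/PPG waveforms, no
activity-dependent storage rate (the wrist tracker is emulated at its
slowest advertised period, 5 s, matching how expected counts are defined),
no clock drift, and no correlation between dropout and signal error.
Passing tests on synthetic data therefore demonstrate the correctness of
the *analysis* (counting, pairing, aggregation, variance decomposition) and
its statistical calibration under a plausible error model — not the field
performance of any real device.

## 3. Analysis conventions

* **Task windows** are closed intervals [start, start + duration] for
  sample membership. The storage grid's last sample falls exactly on the
  window end whenever the period divides the duration, so a half-open
  window would silently drop one sample per task and break the
  observed + missing = expected identity. If two windows abut exactly, the
  shared instant belongs to the later window. Samples in transition gaps
  are discarded everywhere.
* **Minute bins** are anchored at each task's start
  (`minute_index = ⌊(t − task_start)/60⌋`), so per-minute statistics never
  straddle tasks; partial trailing minutes are kept, and the single sample
  allowed on the closed window end is clamped into the last minute bin (a
  120 s task has minute bins {0, 1}, never a spurious third).
* **Pairing** is wearable → reference: each wearable sample is paired with
  its nearest-in-time reference sample if within `max_shift_s` (default
  5 s = half the coarsest 10 s period); reference samples may be reused;
  equidistant candidates resolve to the earlier reference sample
  (deterministic and order-independent). No interpolation: the method
  compares stored samples, it does not resample.
* **Missing epochs** follow the gap rule (gap > period ⇒ one epoch of
  duration gap − period with ⌊gap/period⌋ − 1 missing samples), applied
  uniformly by bracketing each window's samples with virtual sentinels one
  period outside the expected grid — at t = start and
  t = start + (K+1)·period, K = ⌊D/p⌋. This makes leading, interior, and
  trailing losses all detectable (a literal "gap to the window edge" rule
  cannot see a single missing trailing sample when the period divides the
  duration) and makes a fully absent task one epoch of the task's duration,
  so that SpO₂ channels that drop out for whole active tasks report 100%
  missing. Missing percentages are reported to 2 decimals; a zero expected
  count reports as not-applicable (NaN).
* **Exclusion intervals** (manually screened implausible reference
  periods, consumed from a CSV; no automated artifact detector) are
  half-open [start, end) and are applied to reference streams only.

## 4. Agreement statistics

Per participant-minute: median and unscaled MAD
(median(|x − median(x)|)). MAPE per minute is computed from minute
*medians* of paired samples only — both devices restricted to the paired
set, so availability differences cannot bias accuracy — as
100·|w − r|/r with the reference as denominator; minutes with a zero
reference median are excluded and logged. Cluster-level summaries pool all
participant-minutes within a (device, vital, cluster) cell — plus an "all"
cell over every task minute — and report median and IQR with linear
interpolation between order statistics (the numpy default, used
everywhere). Pooling minutes rather than summarizing per-participant
medians was chosen for the larger effective sample and simpler semantics;
with balanced designs the two differ little.

## 5. Repeated-measures Bland-Altman

Implemented as a model/results pair (`BlandAltmanRM(...)` →
`.fit()` → results with `.summary()`). The difference variance is
decomposed by one-way random-effects ANOVA on the differences (formulas in
the README). Numerical and design choices:

* the grand mean d̄ is pair-weighted (mean over all pairs), consistent with
  the pooled RMSE; the alternative (mean of subject means) differs only for
  unbalanced designs;
* a negative method-of-moments between-subject component is clamped to
  zero (standard practice; keeps the total SD real);
* the LoA multiplier is the normal 1.96 with no small-sample t correction
  and no confidence intervals around the LoA (reported-value parity;
  CIs are a possible extension);
* one subject ⇒ error (between-subject variance unidentifiable); all
  subjects singletons ⇒ error (within-subject variance unidentifiable);
  subjects with a single pair are permitted and inform MSB only;
* identical wearable and reference values give d̄ = 0, total SD = 0, LoA
  (0, 0) without special-casing.

Validity is assessed within a preselected cluster per vital sign — HR
during cycling, RR during breathing, SpO₂ and temperature during recovery —
chosen to maximize physiological range at minimal movement artifact.
Because the wearables compute RR with 45–60 s internal averaging windows,
the first 60 s of each breathing task are excluded from the RR analysis
(the warm-up exclusion applies to RR only). The whole analysis is run twice:
on individual paired samples and on participant-minute medians
(aggregation applied after the warm-up exclusion), to quantify what minute
averaging buys.

## 6. Problem sizes and runtime

The default cohort is 20 participants × 18 device-vital streams (≤ 855
samples each), which the full pipeline processes in well under a minute;
the test suite uses 2–3 participant cohorts for pipeline-level checks and
the full 20 for the parameter-recovery check (≈ 2,400 cycling-cluster
pairs), keeping the suite at a few tens of seconds. The brute-force
oracles (O(n·m) nearest-neighbor search, loop-written ANOVA) run on small
randomized inputs, 60–200 trials each.

## 7. Known limitations

* The default schedule's per-task durations are a stand-in (Section 1);
  analyses that depend on exact task lengths should supply their own
  schedule CSV.
* The availability denominator uses each device's nominal (slowest) storage
  period; a device that stores faster than nominal in some states would
  need its true per-state period to avoid availability above 100% (values
  are clamped at 0% missing).
* MAPE is undefined for zero reference medians and asymmetric by design;
  it is not a symmetric percentage error.
* Variance components assume exchangeable pairs within subject; within-
  subject autocorrelation (present in both real data and the generator's
  defaults) inflates MSB relative to an i.i.d. model, which is exactly why
  the minute-level and sample-level analyses are both reported rather than
  corrected analytically.
* No proportional-bias (regression-based) Bland-Altman, no mixed-model LoA
  with covariates, and no diagnostic-accuracy analysis.
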