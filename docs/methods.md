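# Methods

This note documents the models, conventions, and numerical choices behind
`cspike`, and what the synthetic-session validation does and does not
establish about real recordings.

## Task and session model (`cspike.synth`)

A session is a sequence of trials. At trial onset the central fixation dot
appears; after a uniform 400–600 ms fixation it jumps to ±15° (go-signal);
the subject makes a centrifugal (CF) primary saccade after a Gaussian
latency (mean 180 ms, SD 30 ms); the target stays on for a uniform
700–900 ms, after which the dot returns to center and — 100 ms intertrial
interval later — the next trial begins with a centripetal (CP) return
saccade (latency mean 110 ms, SD 50 ms; negative latencies model
anticipatory returns). Nominal trial duration is 1200 ms. Configurations
whose saccadic chains cannot fit inside these epochs raise a
configuration error.

**Saccade kinematics.** Saccades follow a minimum-jerk position profile,
chosen because its peak velocity has the closed form
`v_peak = 1.875·A/D`, which makes every downstream kinematic estimator
testable against an exact oracle. The unfatigued main sequence is affine,
`D = 25 ms + 1 ms/deg · A`, giving 40 ms / ~700 deg/s at 15° and keeping
0.2–2° corrective saccades above the 10 deg/s detection threshold.

**Fatigue.** Repetition scales peak velocity by `r^(k/(n−1))` on trial
`k` of `n` (geometric decay reaching the configured
`fatigue_velocity_ratio` on the last trial); duration is rescaled to
preserve amplitude. With `r = 0.9` the early-vs-late 30-trial median
contrast is 8.6% (the decay law evaluated at the median trial indices),
with duration compensating.

**Endpoint scatter and corrections.** Landing positions get Gaussian
noise (`endpoint_noise_sd`, default 0.6°); when the retinal error
`goal − endpoint` exceeds `corrective_trigger_threshold` (0.5°), a
corrective saccade follows after ~200 ms. Start positions additionally
drift slowly during fixation (`fixation_drift_sd`, default
0.65·`endpoint_noise_sd`), rendered as sub-threshold velocity ramps; this
models fixational scatter inside the 2×2° fixation window and partially
decorrelates amplitude from error. It cannot fully remove the structural
anticorrelation `A ≈ |goal − start|` vs `E = goal − end` within a saccade
class: pooled signed-error bins are therefore amplitude-balanced in their
*means* but remain two-mode mixtures at `15 ∓ e` in distribution. The
amplitude-balance (Kruskal–Wallis) diagnostic is consequently calibrated
only when amplitude is independent of error, which is how the suite tests
it.

**CS trains.** CS times are drawn by thinning from

```
λ(t) = clip( baseline·(1 − suppression(t)) + burst(t) + error_tonic(t)
             + corrective_burst(t) + trial_onset(t), 0 )
```

with: baseline 1 spike/s; multiplicative suppression of the baseline over
−75..+85 ms around each primary-saccade onset (depth 0.8); a Gaussian
burst (SD 10 ms) locked 20 ms after each primary offset with peak
`gain_pref/anti + amplitude_slope·(A − 15°)` (clipped at 0); a tonic term
`error_tonic_gain · E·pd_error` over 50–250 ms from primary offset; a
corrective burst locked to corrective offset, scaled by corrective
amplitude, with the anti-preferred direction receiving a fixed fraction
(0.3) of the gain; and a Gaussian trial-onset bump (SD 30 ms) at
+200 ms, linearly attenuated by the lateness of the preceding CP arrival
and floored at 0. The latent λ(t) is recorded as ground truth.

**CS durations.** Each CS lasts `4.2 ms`, plus one `1.8 ms` terminal
spikelet with probability
`clip(spikelet_base_prob + spikelet_prob_gain·(λ(t) − baseline), 0, 1)`
(defaults 0.3 and 0.05 per spike/s). The linear-with-clipping form is
used rather than a sigmoid so that a zero gain yields exactly
unmodulated durations; the base probability reproduces the bimodal
duration histogram, and the λ-coupling yokes duration changes to rate
changes (including the perisaccadic drop, via suppression).

**SS trains.** Homogeneous Poisson (60 spikes/s) with an enforced pause
after every CS, drawn uniformly from 10–20 ms per CS.

Seeding: behavior, CS, and SS generation use separate child streams of
`numpy.random.SeedSequence`, so each component is independently
reproducible.

## Detection (`cspike.behavior`)

The position trace is zero-phase low-pass filtered (4th-order
Butterworth, 80 Hz — preserving the ~40 ms saccadic profile) and
differentiated with central differences; since both operations are
linear they commute, and saccade endpoints are read off the filtered
trace (at 0.1° sample noise, raw endpoints would exceed a 0.2° amplitude
error far too often). Primary saccades are maximal runs of
|v| ≥ 30 deg/s (runs separated by <10 ms merged, boundary-clipped runs
discarded) with amplitude in 13–17°; correctives use 10 deg/s, duration
strictly >10 ms, amplitude 0.2–2°, must lie between consecutive
primaries, and may not overlap one. Onset/offset are the threshold
crossings themselves. Only the horizontal channel enters amplitudes and
directions (the task has two 180° direction classes); the vertical
channel is retained for QC.

CF/CP labeling is positional (start near center and end near target ⇒
CF; the reverse ⇒ CP), with the active target taken from the bracketing
trial; unclassifiable primaries are labeled `none` with a warning.
Signed error is `goal − endpoint`, rightward positive, so a rightward
overshoot has negative error. Fatigue summaries compare medians of the
first and last 30 saccades per subtype,
`100·(early − late)/early`.

## Rates and windows (`cspike.rates`, `cspike.windows`)

Rates are sums of unit-area Gaussian kernels (σ = 5 ms, truncated at
±5σ) on a 1-ms grid, divided by the event count; the integral of an
isolated spike's rate is 1 to better than 1e-4 on a quarter-ms grid.
All analysis windows are half-open `[start, end)` in ms relative to the
alignment event and are registered centrally in `cspike.windows`.
Population responses are pointwise means across cells with SEM
`sd/√n` (0 by convention for a single cell, flagged). A fast binned
path (1-ms histogram convolved with the sampled kernel) backs the
bootstraps; it matches the exact kernel sum up to the ≤0.5 ms binning
jitter. `align(..., dedupe=True)` attributes each spike to its nearest
event only — required whenever per-spike payloads (CS durations) are
averaged, because overlapping peri-event windows would otherwise count
the same CS twice and correlate neighboring bins.

## Preferred directions and tuning (`cspike.tuning`)

PD_ps uses CS *probability* in 0–100 ms from primary offset; PD_corr
uses *mean rate* in 0–100 ms from corrective offset; PD_error uses mean
rate in −200–0 ms from corrective onset. The differing statistics follow
the original convention rather than unifying them; both are selectable.
Exact ties resolve to +1 with a flag; a direction with no events refuses
assignment. Binned tuning drops bins with fewer than 10 events and fits
an ordinary least-squares line through bin centers, reporting slope,
R², p, and a 95% slope CI.

## Peak and trough timing (`cspike.timing`)

Peak times: per bootstrap repetition, 50 cells are drawn with
replacement (each eligible cell has ≥10 trials in the 5-ms duration
bin), their mean rates averaged, and the argmax taken in a configurable
search window (default 0–200 ms); mean and 2.5/97.5 percentiles over
1000 repetitions are reported.

Troughs: a second-order polynomial is fitted to the −200–0 ms baseline
and a line to the 45 ms preceding the rate peak; the trough is the
earliest real intersection of the two *continuous* fitted functions
between the baseline end and the peak (no grid rounding). Profiles where
the two fits coincide (flat) or no admissible root exists return a
missing value with a diagnostic. The trial-resampling bootstrap draws
1000 trials per repetition (one matrix product per bin for all
repetitions). On noiseless piecewise-analytic profiles the estimator is
exact to ≪1 ms; on Poisson data its accuracy is limited by how the
45-ms pre-peak span interacts with the kernel-rounded peak — validation
uses a modulation with a linear 60-ms rise and sharp 40-ms fall so the
span stays in the linear regime, and attains a ~4 ms mean absolute
error at 1000 trials with ≥95% CI coverage.

## Disentangling error from kinematics (`cspike.disentangle`)

Signed errors are oriented toward the cell's preferred error direction
(positive = PD_error). `pool_comparable_errors` groups events into eight
0.5° signed-error bins spanning ±2° and reports the Kruskal–Wallis
amplitude-balance statistic. `pool_mixed_errors` equalizes the two error
signs within 0.5° amplitude bins by seeded subsampling without
replacement, so the per-bin mean signed error cancels; bins with a
single error sign are excluded. `peak_and_mean_regression` fits the
per-group peak rate (saccade-related) and mean rate (error-related) in
the late window against the group key. The per-cell regression of
window CS *counts* on amplitude and signed error
(`Y = l·A + m·E + c`, OLS via statsmodels, ≥30 events per cell,
rank-deficient designs skipped) runs in the two non-overlapping windows
40–80 ms and 100–250 ms from primary offset; population means of
`l, m, c` and a predicted-count surface over (13–17°) × (±2°) are
exported. Counts rather than rates are the declared default; the
validation reads `l` from the early window (where the burst lives) and
`m` from the late window (where the tonic drive lives).

## CS duration (`cspike.csduration`)

Per cell, CS durations are expressed as percent change relative to the
cell's mean CS duration, averaged in running 50-ms bins advanced in
10-ms steps (non-overlapping stepping available); empty bins propagate
as missing. The population profile averages cells per bin and carries
two uncertainties: the across-cell SEM (display) and a propagated
sampling SEM built from each cell's per-CS duration variance and bin
counts. Modulation epochs are contiguous runs beyond
`baseline mean ± 3·SD`, where the baseline is −200..−100 ms from
saccade onset and the threshold scale is the propagated SEM (floored at
its baseline average, plus the baseline-mean uncertainty term), with a
2-consecutive-bin persistence requirement. The bin-to-bin baseline SD —
the naive reading of the 3·SD rule — rests on only ~2 independent 50-ms
spans and false-triggers on duration-shuffled null data in most runs;
with the propagated scale the shuffle null is clean in ≥95% of
permutations while an injected 5·SD rectangular modulation is recovered
to within one bin. Duration tuning mirrors the rate tuning per
direction class. Duration bimodality is a generator feature; a
histogram QC plot is provided (matplotlib optional).

## Encoding matrices (`cspike.encoding`)

For each of seven parameters (trial-onset timing via CP arrival,
primary amplitude/direction, corrective amplitude/direction, error
magnitude/direction) events are split at the parameter's median (ties to
the lower group) and per-event rates in the parameter's window of
interest are compared with a one-tailed Wilcoxon signed-rank test
(alternative: upper/preferred group fires more). Cells with fewer than
10 CSs in the window are `not_compared`. Pairing convention: groups are
truncated to equal size and paired in chronological event order —
pairing by sorted rate value would positively correlate the paired
differences and destroy the test's level. Zero differences use Pratt's
method with a continuity correction; dropping zeros is measurably
anticonservative (~0.053 at nominal 0.05) on count-derived rates,
whereas the implemented test sits at 0.050 ± 0.002 over 20 000 null
cells. Direction tests hypothesize the preferred direction fires more;
when that direction is assigned from the same window the level doubles —
a circularity the matrix inherits by design and which the calibration
experiments avoid by fixing the direction a priori. Significance flags
(p < 0.05, no multiple-testing correction by default) populate the
cells × parameters matrix; columns are Pearson-correlated pairwise over
co-compared cells, NaN for zero-variance columns.

## Validation scope

The generator reproduces the *statistical structure* of the task —
window occupancies, tuning slopes, timing relations, duration coupling —
but not raw voltages, vertical kinematics (the vertical channel is
noise), blinks or artifacts, cell-to-cell heterogeneity beyond
configured gains, or non-Poisson spike-train history effects. Passing
recovery tests therefore establishes estimator correctness under the
modeled conditions, not performance on arbitrary real recordings.
Problem sizes in the validation experiments (e.g. 200 cells × 300
trials for direction recovery, 10 000 trials for amplitude tuning, 20
runs × 200 bootstrap repetitions for trough coverage, 1500 null cells
for test calibration) were chosen so sampling noise is several times
smaller than the tolerance being checked.
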