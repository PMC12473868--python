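# Methods

This note documents the models, parameter choices and numerical conventions
behind `neurosteps`, and what the synthetic-data experiments do and do not
demonstrate.

## Synthetic gait signals

The generator emulates accelerometry of people with neurological gait
impairment performing unscripted activities of daily living. Per subject, a
bout plan is drawn first: walking bouts of 4–20 s alternate with
exponentially distributed rest gaps whose mean is set so that
`mean_cadence × walking_fraction` equals the subject's target overall step
rate. Inside a bout, step intervals are reciprocals of per-step cadence
draws (normal around the bout cadence, clipped to 0.2–3 steps/s). Each step
is annotated at its foot-reload instant; the annotation set is shared by all
sensor locations.

Per location, the signal is

```
a_vertical(t) = g + Σ_steps A·s_k·w(t − t_k) + 0.25·A·sin(2π·cadence·t)  [+ bursts + noise]
```

with `g = 9.80665 m/s²` exactly, `w` a damped sinusoid (7 Hz carrier, 80 ms
decay, 0.35 s support) normalised to unit peak — a heel-strike-like
transient that keeps the gait fundamental below 3 Hz while placing some
energy above 5 Hz — and `A` a location-dependent amplitude (4.0 m/s² ankle,
2.6 waist, 2.4 lower back, 2.2 thigh, 1.6 chest, 0.9 wrists). The
anteroposterior channel carries the same impulse train at half amplitude
plus a phase-shifted cadence base, so the correlation rule used for axis
assignment has physical signal to find; the third channel carries
half-cadence sway. Step scale `s_k` is 0.4 for shuffling events (annotated
steps without displacement; the paper-gap choice of 40 % is a design
decision, as no per-location signal statistics exist for this population)
and is multiplied by the asymmetry factor on alternate steps. Non-step ADL
movement is modelled as Hann-windowed 0.5–2 Hz bursts of 1–5 s, uncorrelated
with stepping and strongest at the wrists; white noise (0.05–0.10 m/s² sd by
location) is scaled by `noise_scale` (0 gives noise-free oracle signals).
All samples are clipped to ±8 g, the range of the emulated sensor.

Default cohort profiles draw per-subject overall step rates from
N(0.37, 0.145) steps/s (clipped to 0.15–0.75) with cadences of 0.8–1.8
steps/s, shuffle fractions of 5–30 %, asymmetry 0.6–1.0 and 1–4 artifact
bursts per minute, so a 35 min session yields step totals near 775 ± 300 and
a cohort-level rate near 0.37 steps/s. Randomness is organised as one stream
per subject derived from (seed, subject id), plus one per (subject,
location), so cohorts reproduce bit-identically regardless of generation
order or location subset.

**What this does not capture:** biomechanically faithful pathological gait,
gyroscope information, walking aids, sensor detachment, or the true
per-location amplitude statistics of patient data. Passing tests on this
generator demonstrate that the *analysis machinery* is correct and that the
expected orderings (trained regressor ≪ generic baselines) emerge under the
stated signal assumptions — not that any specific accuracy figure transfers
to real patients.

## Preprocessing

Axes are assigned on the **unfiltered** signal: the band-pass filters remove
the gravity component that identifies the vertical channel, so filtering
precedes feature extraction but follows axis assignment. Vertical is the
channel with the largest absolute mean over the whole session (orientation
is fixed per session), sign-corrected positive; anteroposterior is the
remaining channel with the largest absolute Pearson correlation to the
vertical signal; if no non-vertical channel has variance, the lowest-index
one is chosen deterministically.

The three analysis bands are 5th-order Butterworth filters applied
forward–backward (zero net phase; the effective magnitude response is the
squared one-pass response): wide = low-pass 15 Hz, medium = band-pass
0.2–5 Hz, narrow = band-pass 0.5–3 Hz. Filters are implemented in
second-order sections for numerical stability; recordings shorter than the
filtfilt warm-up length are rejected.

Windows start at the recording start and slide with 50 % overlap. A
window's label counts annotated events in the half-open interval
[start, end), so an event on a shared boundary is counted by exactly one of
two adjacent non-overlapping windows. Windows intersecting any excluded
interval (video-unusable time) are dropped entirely from training and
evaluation — partially excluded windows would carry corrupted labels.

## Features

The registry holds, per axis (vertical, anteroposterior): mean, standard
deviation, number of peaks, range, RMS, interquartile range; spectral energy
(DC excluded), dominant frequency, magnitude at the dominant frequency,
spectral entropy; plus cross-axis features: maximum normalized
cross-correlation and its lag (search bounded to ±1 s — gait-relevant lags
only) and the first autocorrelation peak height per axis. Peaks are local
maxima with prominence ≥ 0.1 × the window standard deviation and ≥ 0.25 s
separation (a 4 steps/s ceiling above the 3 Hz gait fundamental). Spectra
are computed on the de-meaned, Hann-tapered window because the short windows
would otherwise leak badly enough to corrupt dominant-frequency estimates;
the taper makes spectral magnitudes only approximately shift-invariant.
Features beyond the canonical set are tagged `extended` in the registry:
they stand in for a published feature list that is not reproduced in full
anywhere accessible, so the registry is a faithful superset of the named
examples rather than an item-for-item match. NaN inputs are rejected, never
imputed.

## Grid scoring and aggregation

Regressors use scikit-learn defaults with a fixed seed — the comparison is
deliberately about the sensing and analysis configuration, not tuning.
Feature standardization statistics are computed on training folds only.
LOSO folds hold out exactly one subject each; when fewer folds than subjects
are requested, the held-out subjects are drawn without replacement from a
seed derived stably from (master seed, configuration label), so grid results
are independent of evaluation order. A cell's score is the **median** across
folds of held-out window RMSE divided by the window length; the median (not
the mean) is what the downstream GLM models.

Subject totals from 50 %-overlapping windows use
`0.5·Σp + 0.25·(p_first + p_last)` on zero-clipped predictions: every
instant is covered by two windows except the two edge half-windows, making
the total unbiased when predictions are locally constant. With
non-overlapping windows the total is the plain sum.

## Gamma GLM over configuration scores

Scores are positive and right-skewed, hence a gamma GLM with log link, main
effects only — the grid (210 cells after excluding the short window) is too
small to support interactions, and the reporting contract is a main-effects
table. Short (0.5 s) windows are excluded before fitting: their score
distribution is bimodal and far worse, violating the gamma assumption.
References are waist, wide band, medium window, GB. Rank-deficient designs
are rejected with the aliased columns named (QR with pivoting). Reported
per level: `exp(β)`, the exponentiated 95 % Wald CI, p-value, and the
predicted RMSE `exp(β₀ + β)` with all other factors at reference.

Model fit is checked by mapping each observation through its fitted gamma
CDF (shape `1/φ`, `φ` the deviance-based dispersion; scale `μφ`) and the
standard-normal quantile function, then testing the resulting quantile
residuals against N(0, 1) with a Kolmogorov–Smirnov test. Because the gamma
parameters are estimated from the same data, this check is conservative
(p-values concentrate above 0.5 under a correct model); it retains power
against gross violations such as bimodal outcomes, which is its purpose
here.

The optimal configuration retains each factor's reference unless some level
is significantly *better* (p < 0.05 and effect size < 1); among such levels
the lowest predicted RMSE wins. This is why a non-significant numerically
better regressor does not displace the reference.

## Baselines

**TCA** thresholds the gravity-referenced acceleration magnitude
(`max(|a| − g, 0)`) at 0.3 m/s². A 0.3 m/s² threshold on the raw magnitude
(≈9.81 m/s² at rest) would fire continuously, so the gravity-subtracted,
half-wave-rectified magnitude is the only meaningful reading; a band-passed
magnitude mode is also provided. Detections are threshold-exceeding
magnitude peaks separated by a 0.25 s refractory period (4 steps/s ceiling).
Counting exceedance peaks rather than raw upward crossings makes the count
provably monotone non-increasing in the threshold — raw crossing counts are
not monotone when noise hovers around a low threshold — while giving
identical counts on clean pulse trains.

**CWT** computes a Morlet transform of the (sign-corrected, de-meaned)
vertical channel over 12 log-spaced scales spanning 0.5–3 Hz. Within
successive 5 s segments — the granularity of the longest analysis window —
the scale with the largest mean squared coefficient is dominant; this is the
mechanism by which the detector adapts to walking speed. Steps are peaks of
the coefficient series at the dominant scale, gated by a relative prominence
(0.25 × the segment's coefficient maximum) and an absolute floor of
0.4 m/s²-equivalent that keeps sensor noise from producing detections in
silence.

The pre-trained SKDH (lower back) and OxWearables (wrist) counters are
exposed only as adapters with an explicit unavailability error; their
internals are external artifacts and are not reproduced.

## Comparison statistics

Per-subject accuracy is `100·|predicted − true|/true`; summaries are median
and IQR (Q3 − Q1) — at n = 7 subjects the mean is fragile, though it is
also emitted. When every algorithm undercounts every subject, median MAPE
and median percentage detected sum to exactly 100. Algorithms are compared
with the Friedman rank test (mid-ranks, tie-corrected; the two-algorithm
case is computed directly since the scipy implementation requires three
groups), gated by Shapiro–Wilk with a caller override for borderline cases.
The exact two-sided Wilcoxon signed-rank floor `2 × 0.5ⁿ` (0.0156 at n = 7)
documents why post hoc pairwise tests cannot survive multiple-comparison
correction at this sample size; they are computed but flagged as
underpowered.

## Problem sizes

The test suite and the acceptance script run on scaled-down synthetic
cohorts chosen as the smallest sizes at which the statistical behaviour
under test is stable: 2-minute sessions and 2–3 subjects for unit tests,
5-minute sessions with 7 subjects for the end-to-end comparison, 200
replicates of the full 210-cell grid for GLM calibration, and a reduced
factor grid (2 locations × 2 bands × 2 windows × 2 regressors) for the
pipeline smoke test. Study-scale runs (35 min × 7 subjects × 7 locations ×
315 cells) use the same code paths through `run_study`.

## Known limitations

* Synthetic amplitude/attenuation profiles are plausibility choices, not
  calibrated to patient data (none are publicly deposited).
* The affine video-to-sensor map assumes linear clock drift between the two
  tap anchors.
* The feature registry approximates, but cannot replicate item-for-item, the
  full feature list used in the original analysis.
* Regressor hyperparameters are library defaults; tuned regressors would
  shift absolute scores (not necessarily orderings).
* LOSO on a single cohort overstates generalizability relative to
  independent-sample validation; the synthetic experiments inherit this
  property by design.
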