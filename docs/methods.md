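# Methods

## The estimation problem

The package treats stress monitoring as a regression problem: predict the
square root of the Baevsky stress index computed from one minute of
NN intervals, using time-domain PRV features computed from only the first
L seconds of that minute, L ∈ {5, 10, 20, 30, 40, 50, 60}. Sliding the
window at a 1 s stride over each 5-minute (post-trim) recording turns every
recording into ~241 samples. Because the window start grid is anchored to
the recording and bounded by the 60 s label segment — not by L — every
window length produces the same samples with the same labels; differences
in cross-validated R² across L are therefore attributable to the features
alone.

## Synthetic cohort model

No human recordings ship with the package, so a seeded generator emulates
the study protocol: `n_subjects` (default 17) × three physiological states
(seated rest, after 2 sets of push-ups, after 4 sets), 6-minute recordings
at 255 Hz.

Beat intervals follow

```
rr_i = mean_rr + a_r sin(2π f_r t_i + φ_r) + a_l sin(2π f_l t_i + φ_l) + ε_i
```

with respiratory modulation (f_r ≈ 0.25–0.35 Hz), a low-frequency
Mayer-wave term (f_l ≈ 0.1 Hz) and white Gaussian jitter ε. Defaults: rest
mean_rr = 850 ms (jitter 30 ms, respiratory amplitude 40 ms, LF 25 ms),
exercise_2set = 650 ms, exercise_4set = 520 ms with variability shrinking
monotonically — the 4-set state stays inside the 60–180 bpm physiological
band and below the ~158 bpm extreme a push-up protocol plausibly reaches.
Published distributional statistics for the real cohort do not exist beyond
that maximum, so these parameters target qualitative fidelity: faster and
more metronomic after exercise, hence median SI(rest) < SI(2 sets) <
SI(4 sets), with rest SI near the conventional 80–150 band. An explicit
integrate-pulse-frequency-modulation model was deliberately not used: the
sinusoid-plus-jitter structure is the simplest that gives all 18 features
nontrivial, state-dependent distributions. Modulation phases are drawn per
recording so analysis windows are not phase-locked; per-subject parameters
get ~5 % multiplicative scatter.

Waveforms are sums of a fixed pulse template at each beat time — a systolic
Gaussian (σ = 90 ms) plus a 30 % dicrotic bump at +300 ms (σ = 100 ms) —
with sinusoidal baseline wander, white noise, and motion artifacts as
3×-amplitude 30 ms spikes at Poisson times (default 0.5/min). The systolic
width matters: a much narrower peak leaves strong second-harmonic energy
inside the 3.0 Hz filter edge at resting heart rates, which splits each
filtered beat into two local maxima and breaks peak detection. Only peak
*times* carry information downstream; the template shape is otherwise free.

What the generator does **not** emulate: realistic pulse morphology change
with vascular tone, respiratory amplitude modulation of the waveform
envelope, non-stationary state transitions within a recording, missing
beats/arrhythmia, and correlated (pink) interval noise. Passing tests
demonstrate that the pipeline's arithmetic and trend behaviour are correct
under the stated beat model, not that accuracies transfer to human data.

## Preprocessing

Trim 30 s from head and tail (device settling), band-pass 0.5–3.0 Hz with a
4th-order Butterworth applied forward–backward (`sosfiltfilt`) so peak
timing is unshifted, then find local maxima with minimum separation
fs/3.0 samples (the band edge implies ≤ 180 bpm) and prominence ≥ 0.3 ×
signal SD. Each peak is refined by a three-point parabolic fit, giving
sub-sample timing; without this, sample-grid quantization alone consumes
the entire two-sample-period interval-accuracy budget.

Outlier screening is a single, non-iterative pass: an interval is flagged
when |interval − mean| / sd ≥ T with T = 2, using the population SD
(ddof 0) of the full trimmed series. Flagged intervals are replaced by the
median of the two nearest surviving neighbours (for two values, their
mean); runs of consecutive flags share the run's flanking survivors, and a
boundary flag copies its single nearest survivor.

Two consequences are worth stating plainly. First, with Gaussian jitter a
fixed T = 2 flags the ~2–5 % of legitimate intervals in the tails — the
replaced count on artifact-free jittered recordings is not zero and cannot
be. Recovery within two sample periods (±7.8 ms at 255 Hz) holds exactly
for *clean* recordings, meaning deterministic (sinusoidal) modulation only:
bounded modulation keeps every |z| below √2·(peak/rms) < 2, so nothing is
flagged. Second, narrow-band filtering smooths fast interval fluctuations;
on jittered recordings the per-interval error is a few ms for ~99 % of
beats with occasional heavier-tailed excursions, which the z-pass then
tends to flag.

## Features and stress index

The 18 time-domain PRV features use these fixed conventions: sample SD
(ddof 1) for SDNN, SDSD and Std HR; NNI50/NNI20 count successive
differences strictly greater than 50/20 ms in absolute value, and pNNI50 /
pNNI20 divide by the number of intervals, reported as proportions in
[0, 1]; heart-rate statistics are computed on per-beat instantaneous rates
60000/nn_i; Median NNI is the median of the intervals themselves — its
occasional textbook description as a median of successive differences
contradicts the feature's name and standard usage, and is not followed.

The stress index uses a histogram with bins [k·w, (k+1)·w) ms anchored at
0, w = 50 ms by default. Mo is the modal bin's **midpoint** in seconds
(the convention is configurable in principle — lower edge or within-bin
mean would shift SI by ≤ ±3 % at w = 50 ms); ties break toward the lower
bin for determinism. AMo is the modal count as a percentage, which makes
SI = AMo[%]/(2·Mo·MxDMn) land in the conventional 80–150 range for relaxed
tachograms — reading AMo as a fraction would not. Mx and Mn come from raw
intervals, not bin edges. All-identical intervals (MxDMn = 0) raise an
error rather than returning infinity; windowed callers drop such windows
and log the count.

## Dataset construction

An interval belongs to the window containing its **ending** beat. Windows
with fewer than 3 intervals, or whose 60 s label segment is degenerate, are
dropped (logged). Feature selection computes, per feature, the agreement
R² = 1 − Σ(ref−short)²/Σ(ref−mean(ref))², pairing every window sample with
its source recording's full-length (5-minute) feature value as the target;
this orientation admits the negative values that badly-agreeing features
produce. Features with R² ≥ 0.6 survive. Selection runs on the pooled
sample set before any CV split, mirroring the study workflow; the optimism
this induces is accepted and documented rather than corrected. "Normalizer"
scaling is per-sample unit-L2 (the standard estimator of that name), not
z-score standardization.

## Models and evaluation

Four scikit-learn regressors at library defaults — ExtraTreesRegressor,
GradientBoostingRegressor, KNeighborsRegressor, LinearRegression — scored
by mean 10-fold CV R², fold shuffling and tree randomness seeded. The
default sample-level folds replicate the study protocol but are optimistic:
1-s-stride windows overlap by up to 59/60 of their span, so near-duplicates
of every test sample sit in the training folds. `group_by_recording=True`
keeps each recording's windows in a single fold; the pooled-minus-grouped
gap is reported by the acceptance script as the leakage audit. R² uses the
test-fold label mean as baseline (scikit-learn's definition) and can be
negative.

## Problem sizes

Simulation scale is configurable; the bundled runs choose sizes that keep
full grids comfortably interactive on one core. The acceptance script runs
the complete protocol shape — 17 subjects × 3 states, all seven window
lengths, all four models, 10 folds — with 240 s recordings (180 s after
trimming, 121 windows each, 6 171 samples per length). The test suite's
trend checks use 3–5 subjects at the same recording length, and a 5-seed
sweep for the tree-vs-linear comparison. Worked-example checks (selection
counts, mean-row averages, SI and feature hand examples) are exact
arithmetic on bundled published grids and run in milliseconds.

## Known limitations

- Synthetic accuracies are far higher than any human-cohort analogue:
  the beat model is low-dimensional and the sample-level CV is optimistic
  by design (see the leakage audit). Trends across window lengths, not
  absolute R² values, are the meaningful output.
- The z-score outlier rule is single-pass and scale-global; it does not
  adapt to slow drifts within a recording.
- Interval recovery degrades gracefully but measurably on heavily jittered
  signals because the 0.5–3.0 Hz band cannot represent fast beat-time
  fluctuations; this is inherent to the filtering choice, not to the peak
  detector.
- Frequency-domain and nonlinear PRV indices are out of scope, as is any
  categorical stress staging.
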