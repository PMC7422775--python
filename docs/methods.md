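# Methods notes

This note records the models, defaults and design decisions behind
`vigilfield`, in the order data flow through the package.

## Frame features and validity

The frame reader targets the CSV dialect of OpenFace-style feature
exporters: one row per frame with a detection-success flag, a tracking
confidence in [0, 1], gaze angles, head pose translation/rotation and
action-unit (AU) intensity columns (`AU01_r` … `AU45_r`).  A frame is
*valid* when the success flag is set **and** confidence ≥ 0.75 (the
floor is configurable and logged).  Invalid frames are carried through
I/O but excluded from every biomarker computation — exclusion happens
before distance computation, not after, so a lost face cannot
contribute phantom dispersion.  Gaze angles are converted from the
upstream radian dialect to degrees visual angle on read (disable with
`gaze_in_radians=False`); timestamps are reconstructed as
`frame / frame_rate` when absent.  All tables are comma-separated with
one header row; whitespace after commas is tolerated, decimal points
only.

## The Sn dispersion estimator

The three movement biomarkers use the Rousseeuw–Croux Sn statistic,
`c_n * med_i(med_{j≠i} d_ij)` with Euclidean `d_ij`.  Conventions:

- `c_n ≡ 1`: no finite-sample bias table.  The statistic is used
  comparatively (across sessions and windows), where a common constant
  cancels.
- Medians of even-length samples are the mean of the two central order
  statistics, for both the inner and outer median (the NumPy
  convention); the inner median runs over the n−1 distances to the
  other points.  No low/high-median variant is offered.
- Fewer than two points yields `None` (a null biomarker), not zero.

The implementation is the O(n²) pairwise matrix (`scipy` `pdist`); at
the ~1,300 frames of a 4-minute 5 Hz session this is a few
milliseconds, so no sub-quadratic refinement is warranted.  Tests
compare it against an independent pure-Python exhaustive enumeration
and assert translation invariance, |a|-scale equivariance and
robustness to relocated outliers.

## Biomarkers and the composite

Sadness sums AU4 + AU15, surprise AU1 + AU2 + AU25 + AU26, blink AU45,
each averaged per frame over valid frames.  Blink is treated as mean
AU45 *intensity*; a binary-presence variant can be had by thresholding
the AU map upstream, but intensity is what the summary equations imply
and is the default.  Response latency averages only responded trials
(missed trials carry no latency information).

Trial windows take frames from `onset − window_frames/frame_rate`
(default 20 frames = 4 s at 5 Hz; the choice is a parameter because
nothing in the problem pins it down) through the end of the trial
(response time, or a 1.5 s response window for misses).  Windows
truncate at session start.  Latency is never computed at window
resolution.

The composite z-scores each biomarker with cohort means and sample SDs
(ddof = 1) and weights by `ω_i = ρ_i / Σ ρ_j`, signed, implementing the
definition literally; a non-positive `Σρ` raises rather than silently
taking absolute values, because weights without a dominant positive
correlation have no meaningful interpretation.  For twice-tested eyes
the two sessions' biomarker estimates are mean-averaged *before*
standardization.  The composite is invariant to affine rescaling of
any input column (the z-scoring absorbs units).

## Perimetric quantities

`dB = 10·log10(3183.1 / DLS_cd/m²)` exactly, with the exact inverse.
Mean sensitivity (MS) is the arithmetic mean of the 24 dB thresholds
of the central 24-2 grid (±15° horizontal, ±9° vertical, 6° spacing);
test-retest error is |MS₁ − MS₂|.  Mean deviation is deliberately not
implemented — MS is the only summary metric here.

Visible trials satisfy `threshold_dB − stimulus_dB > margin_db`
**strictly** (default 3 dB, a doubling of luminance): a trial exactly
at the margin is excluded.  Thresholds are each session's own final
estimates — the best available guess of truth, with the caveat that
they are themselves noisy, so the visible set is indicative rather
than guaranteed.  A 3 dB margin sits far in the upper tail of a 1 dB
frequency-of-seeing curve (detection probability > 0.998), which the
test suite checks by simulation.

## ZEST and compliance weighting

The threshold posterior lives on a 0–40 dB grid in 0.5 dB steps with a
uniform prior by default (a bimodal clinical prior can be supplied as
an array).  The frequency-of-seeing model is a cumulative Gaussian with
σ = 1 dB, guess rate γ = 0.03 and lapse rate λ = 0.03 by default, all
configurable.  Accumulation is in log space; the compliance weight α
multiplies the log-likelihood term, the exact algebraic equivalent of
exponentiating the likelihood.  α = 0 is special-cased to leave the
posterior bit-identical (it also avoids 0 · (−∞)).  Stimulus placement
is the posterior mean (classic ZEST) or a brute-force minimum
expected-entropy sweep; the final estimate is the posterior mean
(posterior mode available).  Stopping combines a trial budget with
optional posterior-SD / entropy criteria; exhausting the budget with a
certainty criterion unmet flags the run "did not complete".

The default α mapping from a compliance estimate θ (e.g. a composite
z-score) is logistic, `α = 1/(1 + exp(k(θ − θ₀)))` with k = 2 and
θ₀ = 1.5: a subject at the cohort mean (θ = 0) keeps α ≈ 0.95, while
θ = 3 (grossly non-compliant) drops to α ≈ 0.05.  The transform's shape
is an implementation choice — any monotone map into [0, 1] is
admissible — and both constants are parameters.

## Synthetic data generator

The generator is the package's study-condition definition, not a
tuning surface.  Structure:

- **Compliance process**: a two-state Markov chain (attentive/lapsed)
  at the 5 Hz frame rate.  The lapsed→attentive probability is 0.05
  per frame (mean lapse bout 4 s); the attentive→lapsed probability is
  derived from the stationary occupancy, which interpolates linearly
  with a subject trait in [0, 1] from 0.02 to 0.45.  This is the
  simplest process that produces both window-level biomarker/lapse
  coupling and session-level composite/error coupling.
- **Emissions**: gaze/head channels are Gaussian jitter around subject
  baselines with state-dependent SDs (attentive SDs grow linearly with
  the trait — e.g. gaze 0.5 + 1.5·trait deg — and are multiplied by 3
  while lapsed); AU intensities are Gaussian with trait-dependent means
  plus a lapsed-state boost, truncated at 0; latencies are Gaussian
  (clipped at 50 ms) with trait- and state-dependent means.  1% of
  frames are marked invalid to exercise the validity path.  Magnitudes
  are order-of-magnitude choices for a seated adult at a laptop, not
  claims about any particular dataset.
- **Trials**: 24 locations interleaved in shuffled rounds, 6 trials
  per location (144 per session, ~4.3 min at a 1.8 ± 0.3 s pace).
  Responses come from the cumulative-Gaussian observer at the true
  threshold; while lapsed, detections are suppressed with probability
  0.6.  Each location runs a standard (α ≡ 1) ZEST online, and the
  session's threshold grid is the final posterior means — so
  test-retest MS error *emerges* from the lapse process through the
  actual estimation stack rather than being injected.  A shortcut mode
  (`fast_ms_noise_sd`) skips the ZEST runs and injects trait-scaled
  Gaussian threshold noise for cheap unit tests.
- **Cohorts**: traits uniform on [0, 1]; every random draw flows from
  the single config seed through spawned per-subject/per-session
  substreams, so identical configs are bit-identical.

With the defaults, a 40-subject cohort yields a composite–error
correlation around 0.45–0.5, a visible-trial fraction near 30% and a
visible-trial miss rate near 5% — the same regime as webcam perimetry
compliance studies.  What passing tests on this generator do *not*
show: robustness to real tracking artefacts (dropouts, lighting,
glasses), non-Gaussian movement distributions, learning/fatigue trends
within a session, or eye-within-subject correlation in patients — the
generator has none of these.

## Statistical analysis choices

- Pearson correlation per biomarker and for the composite; scatter
  slopes are geometric-mean (reduced major axis) regressions,
  `sign(r)·SD(y)/SD(x)` through the centroid, appropriate when both
  axes carry error.
- Outliers: a manual exclusion hook with mandatory logging; no
  automatic detection.
- Trial-level lapse models: binomial logistic fits of hit/miss on the
  *raw* biomarker (maximum likelihood via `statsmodels`, tolerance
  1e-8, 100 iterations), with the likelihood-ratio χ² (1 df) against
  the intercept-only model.  An outcome class with fewer than two
  members, or perfect separation, yields a flagged result with no
  p-value.  Binned summaries use four log₁₀-spaced bins over the
  positive value range with Wilson 95% intervals (Wilson behaves well
  at the hit rates near 1 that dominate here); non-positive values
  (degenerate inputs only) fall into the first bin and are logged.
- No multiple-comparison correction and no mixed-effects clustering of
  eyes within subjects; trial-level pooling treats trials as
  exchangeable across eyes.

## Problem sizes in the shipped tests and acceptance script

Cohort-level checks use 40 subjects × 2 sessions × 144 trials
(~11,500 trials, ~3,300 visible); the ZEST comparison uses 200 paired
replicates of 30 trials; the Sn cross-check enumerates hundreds of
random instances up to n = 50, d = 3; calibration of the χ² test uses
500 null replicates of n = 2,000.  These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping a full run in
a couple of minutes.

## Known limitations

- Sn is computed per session/window without temporal modelling; slow
  drifts and oscillations are indistinguishable.
- The α mapping is heuristic; nothing calibrates θ₀/k against observed
  lapse probabilities.
- The composite is fit and evaluated on the same cohort (by design,
  mirroring the small-sample approach it implements); its r is
  optimistic relative to out-of-sample use.
- The generator's lapse process is memoryless beyond the two-state
  chain; real attention has longer-range structure.
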