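# Methods

## The measurement

A gait cycle — heel contact to the next heel contact of the same foot —
is recorded as 201 angular samples for each of 15 kinematic channels
(pelvis, hip, knee, ankle, forefoot × abduction-adduction,
flexion-extension, rotation). `gaitpe` quantifies the *ordinal
complexity* of each channel's trajectory with permutation entropy (PE):
the series is cut into maximally overlapping windows of length D
(delay τ between samples), each window is reduced to the permutation
that sorts it (ties broken by time index), and

PE = −(1 / log₂ D!) · Σᵢ pᵢ log₂ pᵢ

over the relative pattern frequencies pᵢ. PE is 0 when a single pattern
occurs (any monotone series) and 1 when all D! patterns are equally
frequent (long i.i.d. noise). Because only ranks matter, PE is invariant
to positive affine rescaling — degrees vs radians is irrelevant — and
needs no binning or thresholds.

**Defaults: D = 3, τ = 1.** With 201 samples there are 199 windows; at
D = 4 the 24 possible patterns would each receive ~8 windows on
average, too few for stable frequency estimates. A rule of thumb
implemented in `recommended_min_length` asks for at least (D+1)! = 24
samples.

**Region count.** N − (D−1)τ windows are formed (the maximally
overlapping convention), so a 5-point series at D = 3 yields 3 windows.

## Multi-scale analysis

`coarse_grain(x, v)` replaces non-overlapping blocks of `v` consecutive
samples by their mean (⌊N/v⌋ output samples, remainder discarded;
v = 1 is the identity). PE of the coarse series as a function of
v ∈ {1..22} separates fast from slow complexity: white jitter is
attenuated ≈ √v by the averaging while the macroscopic envelope
survives. The per-channel attenuation of a two-group entropy gap is

ΔMSE = [MSE_cp(22) − MSE_ctrl(22)] / [MSE_cp(1) − MSE_ctrl(1)],

near 0 when the group difference lives purely in high frequencies, near
1 when it persists at every scale. v = 22 is the largest scale leaving
a usable coarse series from 201 samples — but note ⌊201/22⌋ = 9 is
below the 24-sample rule, so per-cycle entropies at the coarsest scales
are noisy. Two group-curve estimators are therefore provided:
`pooling="mean"` (mean of per-cycle PE, the default) and
`pooling="pooled"` (pattern counts pooled over all the group's cycles
before taking one entropy — stable at any scale). Scales whose coarse
series cannot be embedded are reported as NaN, never raised.

## Synthetic cohort generator

No public joint-kinematics dataset accompanies this problem, so
`gaitpe.synthetic` generates cohorts carrying exactly the statistical
structure the pipeline is designed to detect. Defaults mirror the
reference cohort shape: 27 controls, 53 patients staged GMFCS
I:5/II:19/III:23/IV:6, 4–10 cycles per subject (2–5 per side).

Per channel, a cycle is

envelope + shape noise + white jitter,

* **envelope** — a triangle wave rising over a fraction r ∈ (0.87, 0.93)
  of the cycle and falling over the rest, circularly smoothed by a
  Gaussian of 3.5 samples, scaled to a half-amplitude of 12–36°. The
  long-slow/short-fast asymmetry echoes stance/swing structure and is
  what gives the noise-free envelope a low PE (≈ 0.25–0.29): a
  symmetric wave cannot fall below log₂2/log₂6 ≈ 0.39 because its two
  monotone patterns are balanced. Subjects perturb amplitude, offset,
  rise and phase around a per-channel population template.
* **shape noise** — per-cycle random cosines at harmonics 1..4
  (`shape_noise_sd` = 0.5° per harmonic, decaying 1/k): slow
  cycle-to-cycle variability that barely moves PE.
* **jitter** — white noise with sd = `jitter_sd0` + `jitter_gain` ×
  severity, severity being 0 for controls and 1–4 for GMFCS I–IV.
  Defaults 0.05° and 0.08°/stage put per-channel control PE near
  0.25–0.4 and spread the stages monotonically up to ≈ 0.9;
  `SyntheticConfig.strong_effect()` doubles the gain to 0.16°/stage.
  `signal_channels` confines the severity term to chosen channels, which
  is how targeted feature-importance fixtures are built.

Severity acting *only* through high-frequency jitter is the minimal
mechanism consistent with the whole analysis: it raises patient PE at
scale 1, and coarse-graining wipes the gap out, driving ΔMSE toward 0.
An optional `speed_jitter_gain` adds extra jitter to
slower-than-expected walkers (patients only by default), the mechanism
behind a speed × condition interaction.

Subject metadata follows the severity gradient: walking speed
1.25 − 0.15·severity ± 0.08 m/s (truncated > 0), limb length
U(0.5, 0.9) m, GDI 100 − 8·severity ± 3, GPS 5 + 2.5·severity ± 1, each
MAP item 5 + 1.5·severity ± 1. All parameters are invented — no
clinical reference values exist for them — and everything is
deterministic given `seed`.

**What the generator does not emulate:** real kinematic waveform shapes
(double-bump pelvic curves, biphasic knee flexion), inter-channel
correlation of noise, autocorrelated measurement error, left/right
asymmetry, or severity effects on the envelope shape itself. Passing
tests therefore demonstrate that the pipeline recovers the designed-in
ordinal structure, not that clinical effect sizes would reproduce.

## Inference

* **Channel t-tests.** Welch's two-sided statistic per channel, on
  per-subject mean PE by default (repeated cycles of one subject are
  not independent; per-cycle mode is available for sensitivity
  analysis). Familywise error over the 15 channels is controlled at
  α = 0.01 by the Šidák per-test level 1 − (1 − α)^(1/15) ≈ 6.70×10⁻⁴.
* **Mixed models.** Three families, each with a random intercept per
  subject, fitted by REML (statsmodels, BFGS): (1) per-cycle PE on
  GMFCS indicators with controls as reference; (2) per-cycle PE on
  normalized speed (walking speed / limb length, 1/s), condition
  (cp = 1) and their interaction; (3) GDI/GPS (or a MAP item, paired
  with its corresponding channel) on PE, patients only. Wald normal
  approximations provide p-values; they are labelled approximate, and
  the primary uncertainty statement is the bootstrap interval.
* **BCa cluster bootstrap.** Whole subjects are resampled with
  replacement (1000 replicates by default), resampled clusters receive
  fresh ids, the model is refitted, and bias-corrected accelerated
  intervals are formed with jackknife-over-subjects acceleration. The
  bias-correction proportion is clipped to [1/(B+1), B/(B+1)];
  replicate sets with zero spread yield a zero-width interval at the
  point estimate; non-convergent replicates are dropped (an error above
  20%). Replicate refits are warm-started at the full-data optimum with
  a loosened gradient tolerance on the variance profile — the fixed
  effects are the GLS solution given the variances and were verified
  unchanged to 10⁻¹⁴ against fully converged refits.
* **Calibration study sizing.** The bootstrap-coverage check uses 60
  balanced clusters (12 subjects × 5 stages, 2 cycles each), 200
  bootstrap replicates and 100 simulation replications. Pilot runs
  showed the expected small-sample undercoverage with ~40 clusters
  (≈ 85–90%); 60 balanced clusters is the smallest design in which
  BCa's nominal 95% behaviour is observable.

## Classification

* **Condition (control vs CP).** Each subject is its 15-vector of
  channel-mean PE. A random forest (500 trees, √15 features per split,
  unlimited depth — conventional defaults, all configurable) is
  validated by leave-one-out over subjects; out-of-fold CP
  probabilities are pooled into one ROC curve and AUC. Feature
  importance is the AUC drop after deleting a channel and rerunning the
  entire LOO procedure; redundant channels show drops near zero or
  below even when individually discriminative.
* **GMFCS staging.** Five ordered classes (healthy, I–IV) on per-cycle
  vectors. Cross-validation leaves out *all cycles of one subject* by
  default so subject identity cannot leak (cycle-level LOO available).
  Agreement is the linearly weighted Cohen's kappa (quadratic optional)
  with a percentile CI from resampling subjects over the out-of-fold
  predictions (2000 replicates). Per-channel importance is the mean
  increase in training-set misclassification over 10 random
  permutations of that channel — an in-sample permutation importance,
  adequate for ranking channels.

## Numerical choices and edge cases

* Ties in ordinal patterns: stable sort, earlier sample ranks first —
  deterministic, and a measure-zero event for continuous angles.
* 0·log 0 ≡ 0; absent patterns simply drop from the entropy sum (no
  pseudo-counts). Entropies are clipped to [0, 1] against rounding.
* Constant series have one pattern at every scale → PE 0, no special
  casing.
* CSV round trips are exact: floats written with 17 significant digits
  and parsed with round-trip precision; row and column order are
  deterministic, so equal cohorts produce byte-identical files.
* ΔMSE raises on a zero scale-1 gap (undefined ratio) and is invariant
  to which group is labelled patient (numerator and denominator flip
  sign together).

## Problem sizes used in the test suite

Unit tests run on miniature cohorts (10 subjects, 2–4 cycles). The
end-to-end recovery checks use the full default cohort (80 subjects,
~570 cycles), 100-series Monte-Carlo batches for multiscale trends, 200
random series against the brute-force entropy oracle, 200 label
permutations for the familywise type-I check, and the calibration
design above for bootstrap coverage.
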