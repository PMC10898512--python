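# Methods

## Scientific question and overall design

When an observer rates how vividly they perceived a masked stimulus — on the
4-level perceptual awareness scale (PAS): no experience (NE), weak glimpse
(WG), almost clear experience (ACE), clear experience (CE) — is the neural
signature of that vividness *content-invariant* (shared across stimulus
identities) and *graded* (neighbouring ratings more similar than distant
ones), or specific to the perceived content and/or discrete?

No suitable raw data can be redistributed, so the package answers a
parameter-recovery question instead: if sensor- or voxel-level data are
generated with a *known* representational geometry, do the analyses —
model-RDM representational similarity analysis (RSA), cross-condition
temporal-generalization decoding, and searchlight decoding with
permutation-plus-bootstrap group inference — recover that geometry and only
that geometry?  Every analysis therefore ships with a generator whose ground
truth is exact, and the acceptance surface is recovery (the generating model
wins; invariant codes transfer across stimuli; null data produce calibrated
false-positive rates).

## Behavioural simulation

The masking experiment titrates stimulus contrast on a 26-level grid (2–77%
in 3-point steps).  Block 1 uses a fixed rule (+1 level on an identification
error, −2 after two consecutive correct); later blocks apply the rule of the
currently least-used PAS rating — NE: −3/+1, WG: −2/+1, ACE: −1/+2, CE:
−1/+3 (decrement after two correct / increment on error) — so the staircase
actively balances rating usage.  The two-correct counter resets when a
decrement fires; ties in "least used" go to the lower rating; the level
index is clamped to the grid; counting of rating usage is cumulative over
the session.  The staircase starts at the middle level (index 13).

The observer model is deliberately minimal: identification is Bernoulli with
`p = lapse/2 + (1 − lapse)·logistic(slope·(c − threshold))` (accuracy 0.5 at
threshold), and the PAS rating is the ordinal bin of an internal signal
`c + N(0, σ)` against three fixed cutpoints.  Defaults (threshold 25%, slope
0.12 per %, lapse 0.02, cutpoints 18/30/42%, σ = 9) were chosen once so that
a staircased session of 11 × 72 trials yields all four ratings at ≥ 5%
frequency for essentially every seed; they are not fitted to anything.

## Embedded representational codes (MEG-like data)

Epoched data are trials × sensors × samples at 250 Hz (inclusive endpoints;
−200..2000 ms = 551 samples; a −450 ms variant is available via
`epoch_ms`).  Signals are planted as `amplitude × pattern × envelope(t)`
plus sensor noise (iid Gaussian, optionally AR(1) in time); the envelope is
a raised cosine over the embedding window, and `snr` is the peak pattern
norm divided by the noise SD (interpreted as an absolute amplitude when the
noise SD is zero).

A scale-invariant subtlety dictates the construction of the graded codes:
the neural RDM uses Pearson distance across sensors, which ignores pattern
amplitude, so a code that only *scales* one fixed pattern with the rating
would produce a flat (all-zero) noiseless RDM.  Graded codes are therefore
*angular*: the four rating patterns lie on an arc in sensor space, 30°
apart, built from zero-mean orthonormal basis vectors (QR of centred
Gaussian draws, sign-fixed for reproducibility).  The noiseless Pearson
distance between ratings i and j is then exactly `1 − cos(|i−j|·30°)` — a
strictly increasing function of the rating difference — and the maximal
within-stimulus separation (90°) equals the distance between the orthogonal
per-stimulus planes used by the content-specific code, so the noiseless
geometries match their model RDMs rank-for-rank.  Amplitude additionally
grows linearly with rating (0.25–1.0 of `snr`), which feeds the decoders
without affecting the correlation geometry.  The four schemes:

- `abstract_graded` — one arc shared by both stimuli (content-invariant,
  graded);
- `abstract_discrete` — four mutually orthogonal patterns shared by both
  stimuli, equal amplitude;
- `specific_graded` — one arc per stimulus in orthogonal planes;
- `null` — no rating-dependent signal.

Optional confounds: a contrast-proportional pattern (exercising the
contrast-regression control) and a PAS-proportional constant offset before
0 ms (exercising the no-baseline-correction analysis).  Both use basis
vectors orthogonal to the code patterns so that their removal is testable in
isolation.

What the generator does *not* emulate: realistic sensor covariance and head
geometry, evoked components unrelated to vividness, trial-to-trial latency
jitter, eye or cardiac artifacts, or inter-subject variability in code
topography beyond a fresh random basis per subject.  Passing recovery tests
therefore show that the analysis chain is correct and calibrated, not that
real MEG data would behave this cleanly.

## fMRI-like data

Trialwise betas live on a masked 3D voxel grid (ellipsoidal mask by
default).  Regions are spheres (or explicit voxel sets) carrying:

- `visibility_invariant` — a fixed zero-mean unit voxel pattern scaled by
  the visibility weight (0, 1/3, 2/3, 1 for ratings 1–4), identical for both
  animacy classes;
- `content` — an animate/inanimate (+/−) pattern scaled by the
  content-visibility weight (0, 0.1, 0.7, 1): stimulus identity is
  essentially unavailable below the awareness threshold and rises steeply
  with a clear percept, so content is decodable only on high-visibility
  trials;
- `visibility_specific` — a separate visibility pattern per animacy class
  (content-specific visibility information, the foil for the
  cross-vs-within comparison).

A forward BOLD route (canonical double-gamma HRF, one regressor per trial
plus intercept, ordinary least squares per voxel) validates that the
beta-series abstraction is consistent: recovery is exact for well-separated
onsets without noise, and degrades monotonically with noise.

## RSA chain

Condition patterns are estimated by dummy-coded least squares (one one-hot
indicator per condition, no intercept), which equals the per-condition trial
mean — asserted against a normal-equations oracle.  The 8×8 neural RDM is
`1 − r` (Pearson across sensors) per time point; a zero-variance pattern has
no defined correlation and receives the neutral distance 1 (logged).  RDM
cells are smoothed over time with a 60 ms uniform kernel (15 samples at
250 Hz); the default edge rule truncates and renormalises the kernel
(`reflect` available) so constant series pass through unchanged.

Model fit is Kendall's tau over the 28 strictly-lower-triangle cells
(diagonal excluded).  Tau-a (pair-count denominator `n(n−1)/2`) is the
default for the headline time courses, following the usual RSA convention
for models with tied values.  The tau variant matters for *model
comparison*, though: on exactly discrete neural data the graded model's
extra rank distinctions fall entirely on tied neural cells, so
tau-a(neural, graded) and tau-a(neural, discrete) have identical
expectations and the discrete geometry can never win a tau-a comparison.
The tie-corrected tau-b normalises by the number of non-tied pairs in each
input, credits the coarser (tie-rich) model when the data carry no finer
structure, and recovers all three testable geometries; the model-recovery
suite therefore compares models on tau-b while reporting tau-a alongside.
Both variants are implemented and cross-checked against an independent
implementation.  A
constant input yields tau 0 (logged) — this keeps time courses complete
outside the response window.  The uniform specific-discrete model cannot be
rank-correlated and is rejected if passed directly; it is the implicit
tau = 0 null, exactly as in the group tests.  Rank correlation makes every
comparison invariant to monotone transforms of model values, which is tested.

The shuffle-and-blend control produces, per permutation, a
`shuffled_discrete` RDM (uniformly permuted lower triangle of the
abstract-discrete RDM) and a `shuffled_graded` partner whose four
high-similarity cells carry 0 with a graded blur: immediate lattice
neighbours 1, diagonal neighbours 2, all other cells 3 (overlaps take the
minimum).  The blur is computed around the *unshuffled* zero cells and the
same permutation is then applied to both matrices.  This order matters: the
blur template is fixed, so every lower-triangle cell has an identical value
distribution over permutations and the expected rank correlation with any
fixed RDM is exactly zero, while the value multiset — the variance and
frequency profile the control exists to match — is preserved.  Blending
*after* shuffling (available as `order='blend_after_shuffle'`) clips
neighbourhoods at the triangle borders, making expected cell values
position-dependent; on clean synthetic cohorts that residual structure is
measurable (≈ +0.006 mean tau against lattice-structured RDMs) and a
15-subject cluster test flags it, which is why it is not the default.  With
either order the blurred multiset contains more maximal cells than the
abstract-graded RDM (lower-triangle variance ≈ 1.2 vs 0.82), a consequence
of the 8×8 lattice geometry; the rank-based analyses are unaffected.

Classical MDS uses Torgerson double-centering of squared dissimilarities and
keeps the positive-eigenvalue dimensions (fewer than requested if necessary,
logged); sign and rotation are indeterminate, so tests align configurations
by Procrustes before comparing.

## Decoding

The decoder is multiclass LDA with the pooled within-class covariance shrunk
toward `ν·I` (`ν = trace(S)/p`).  The shrinkage intensity is the analytic
Ledoit–Wolf estimate computed on class-centred training data (cross-checked
against an independent implementation), clipped to [0, 1], with degenerate
inputs (no within-class degrees of freedom) mapping to 1; the fMRI analyses
use a fixed 0.2.  At intensity 1 the rule reduces to nearest-class-mean,
which is tested algebraically.  Priors are equal because folds are balanced
by construction: each class is randomly down-sampled to a common per-fold
count; fold disjointness and per-fold class balance are asserted on every
run.  Decoding is invariant to common affine feature transforms, as LDA
should be.

Temporal generalization trains one decoder per time point (data first
boxcar-smoothed over 7 samples = 28 ms) and tests it at every time point.
Within-condition decoding cross-validates on one stimulus's trials.
Cross-condition decoding trains on one stimulus and tests on the other —
and, although the test data are never seen in training, it still applies the
same fold structure to *both* stimuli (train on k−1 folds of the train
stimulus, test on fold f of the test stimulus) so that training-set sizes
match the within scheme; without this, the cross scheme trains on ~25% more
trials and shows a systematic accuracy advantage (≈ +0.025 measured on
content-invariant synthetic data) that would contaminate the cross-vs-within
comparison.  The per-sample confusion matrix (row-normalised over folds)
exposes the distance effect: under a graded code, neighbouring ratings are
confused most.

The fMRI visibility split uses the subject's standard (interpolated) median
rating: ratings strictly below the median are "low", the rest "high", so a
subject using 2/3 on half the trials and 4 on the other half (median 3.5)
maps 2 and 3 to low and 4 to high, and a degenerate single-rating subject is
all-high.  Subjects with fewer than 10 trials in any animacy × visibility
cell are excluded.  Searchlights are Euclidean spheres of radius 4 voxels
(257 voxels on a full lattice); out-of-mask sphere voxels are dropped rather
than zero-padded, so edge searchlights have fewer features.  ROI analyses
select the 200 in-ROI voxels with the highest mean visibility-decoding
accuracy across the four directions (stable tie-break by voxel order) and
decode animacy separately per visibility split.

## Group inference

Cluster-based permutation tests compute a one-sample t per point, form
clusters from points with p below the cluster-forming alpha (0.05) by
temporal adjacency in 1D or 4-connectivity over the two time axes in 2D, and
summarise each cluster by the sum of its t values ("maxsum").  The null is
the maximum cluster statistic over whole-map per-subject sign flips —
flipping per time point would break exchangeability and is not offered — and
cluster p-values use the `(1 + exceedances)/(1 + n_perm)` convention, so they
are never zero.  Tails: one-sided (greater) for accuracy-vs-chance and
tau-vs-zero, two-sided for paired comparisons; both configurable.  Paired
comparisons are implemented as explicit within-subject condition swaps and
are tested for exact agreement (clusters and statistics; p within resampling
error) with sign-flipping the within-subject differences.  Family-wise error
of the 1D test on pure noise is verified to sit in the exact binomial 95%
band around the nominal 0.05 over 200 simulations.

Searchlight maps use a Stelzer-style null: each subject contributes 25
label-permuted decoding maps (10 in the reduced profile); each of 10,000
bootstrap samples (2,000 reduced) draws one permuted map per subject and
averages, and the voxel p-value is the `+1`-convention exceedance
probability of the observed group mean.  Averaged cross-direction maps are
tested against averaged nulls, and the cross-minus-within comparison
differences the maps before the bootstrap, exactly mirroring the observed
statistic.  Voxelwise p-values are Benjamini–Hochberg corrected at q = 0.01;
the corrected false-positive voxel proportion under the null is verified to
stay at or below q on average.

## Problem sizes, profiles and determinism

The `full` pipeline profile mirrors the reference parameters (epoch
−200..2000 ms, 1,000 cluster permutations, 1,000 shuffle permutations per
subject, 25 × 10,000 searchlight null, radius-4 searchlights, 11 × 72 trials,
15 subjects).  The default `reduced` profile is the package's desk-scale
choice for routine runs and CI: shorter epochs (−200..600–800 ms), 8
subjects, 6 × 48 trials, 30–50 sensors, 10³ voxel grids with radius-2
searchlights, 500 permutations, 10 × 2,000 null.  The recovery test suites
use similar scaled-down sizes (20 cohorts as specified; 15 subjects for the
RSA recovery, 8 for the temporal-generalization recovery; epochs of
−100..400–500 ms).  Statistical conventions (cluster alpha, FDR level, fold
count, kernel lengths) are never scaled, only problem sizes.

All randomness derives from explicit seeds; per-stage seeds come from a
documented counter scheme over one master seed, so any stage can be re-run
in isolation and a repeated run reproduces every output byte (tested).
Ledoit–Wolf batched fits across time points are algebraically identical to
per-time-point fits (tested to 1e-10).

## Known limitations

- The generators produce i.i.d. Gaussian noise with homogeneous
  between-subject structure; group tests on such cohorts are more sensitive
  than on real data, so "no significant cluster" outcomes here are a
  calibration statement, not a power statement about real experiments.
- The shuffled-control variance profile cannot exactly match the
  abstract-graded RDM's on an 8×8 lattice (see above); rank-based analyses
  are unaffected.
- Searchlight decoding is exact but not optimised for large grids; full-size
  (radius 4, 16³) runs are minutes per subject-direction, not seconds.
- The trialwise GLM assumes known onsets and a canonical HRF; HRF
  variability and nuisance regressors are out of scope.
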