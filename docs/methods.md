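# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `datfuse`, in the order the pipeline runs.

## Phantom cohorts

The phantom generator is first-class, tested code: it defines the study
conditions under which every statistical claim of the test suite holds.

**Geometry.** Volumes default to 79×95×78 voxels at 2.0 mm isotropic. A
large "brain" ellipsoid (semi-axes 0.44/0.46/0.44 of the grid) bounds the
background; two striatum-like ellipsoids (semi-axes 0.10/0.14/0.11 of the
grid, centred at 0.33/0.67 of the x extent) stand in for the merged caudate
and putamen of each hemisphere. The right ellipsoid is the exact mirror of
the left through the sagittal midplane, so hemispheres have identical voxel
counts and mirror symmetry is exact — which is what makes the hemisphere
swap and centre-of-mass oracles analytic. All geometry scales with the
grid, so tests run on down-scaled grids (typically 24×30×24 or 40×48×40)
with the same structure; the methods the package implements are resolution
independent, and problem sizes in the test suite were chosen so the full
suite completes in minutes.

**Intensity model.** Background voxels are i.i.d. α-stable with default
(α=1.8, β=0.5, γ=5.41, δ=28.42): dispersion and location mirror the values
reported for normalized clinical uptake images; α and β (not reported
anywhere) are set to a moderately heavy-tailed, right-skewed law, which is
what count-limited emission tomography backgrounds look like. Striatal
voxels are Gaussian with mean 100 (controls) and SD 10. Patients carry mean
100/`striatum_contrast` (default contrast 2, matching the roughly halved
tracer binding seen in Parkinsonian striata), redistributed between
hemispheres by ±`asymmetry` (affected side ×(1−a), other ×(1+a), affected
side chosen at random per patient). The redistribution is mean-preserving
by construction so the bilateral HC/PD mean ratio equals the configured
contrast exactly in expectation. Each subject is finally scaled by a
lognormal gain (log-SD `gain_sd`, default 0.15) emulating dose/scanner
variability — the quantity the intensity normalization must remove.
Negative background draws (rare at the default parameters) are clipped to
zero, since uptake images are non-negative.

**Biomarkers.** Each source is standard-normal noise per test;
the first ⌈`informative_fraction`·n⌉ columns get a mean shift of
`effect_size` SD in patients. Defaults (4 CSF, 34 RNA, 1 Serum test;
fraction 0.25; effect 0.3; 10% missing cells, missing completely at random)
mimic panels that are only weakly informative — the regime in which
windowed fusion matters. Real biomarker data additionally have correlated
tests, batch effects and informative missingness; none of these are
modelled, so passing tests demonstrate correctness of the machinery, not
clinical performance.

**Randomness.** Every draw descends from one integer seed through
fixed-entropy child streams (`(seed, 0, subject_index)` for volumes,
`(seed, 1, source_index)` for tables), with a documented draw order inside
each stream. Identical config + seed ⇒ bit-identical cohorts, and adding
subjects or sources never reshuffles earlier draws.

## α-stable intensity normalization

**Parameterization.** All parameters use the continuous S0 convention, in
which the family is a true location-scale family for fixed (α, β):
x → c·x + d maps (γ, δ) → (c·γ, c·δ + d). This matters because the
normalization is exactly an affine map; in the S1 convention the location
parameter's meaning depends discontinuously on α near 1. SciPy's default S1
is converted internally.

**Background mask.** Voxels above 10% of the volume's 99th-percentile
intensity, restricted to the largest connected component, holes filled,
striatal labels removed. A user-supplied mask can be used instead by
fitting on any voxel selection directly.

**Fitting.** Two stages. (1) McCulloch-style quantile matching gives all
four parameters — deterministic, fast, and affine-equivariant by
construction. (2) A numerical maximum-likelihood refinement of (γ, δ) only,
holding (α, β) at the quantile estimates: because the family is
location-scale for fixed shape, the log-likelihood needs the standard pdf
only once, evaluated on a 512-point grid uniform in asinh(z) (dense core,
and linear extrapolation in asinh matches the power-law tail decay
log f ≈ −(1+α)·log|z|), then Nelder–Mead over (γ, δ) with tolerances 1e−6
(max 400 iterations). Only γ and δ enter the normalization transform, which
is why the refinement concentrates on them; full four-parameter ML over
numerically integrated stable densities is orders of magnitude slower with
no benefit to the transform. Samples larger than 100 000 are thinned by
order statistics before refinement. If the optimizer fails, the quantile
estimate is kept and flagged in the parameter provenance
(`method="quantile"` vs `"quantile+ml"`). The sample floor is 100 voxels;
constant samples are rejected.

On simulated images the fit recovers (γ, δ) with median relative error
well under 5% at 10⁴ samples, and re-fitting a normalized cohort recovers
(γ\*, δ\*) per image within 5% — both asserted by the test suite.

## Morphological features: boundary semantics

All conventions are deliberate, documented and tested:

- "1%" subsets contain ⌈0.01·n⌉ voxels.
- Threshold counts use strict `>`; a constant ROI therefore yields 0 at the
  1.0·m threshold.
- Ties when selecting the N most intense voxels break by raster (C-)order.
- Projections collapse along axis 2 (axial), 1 (coronal), 0 (sagittal);
  ellipse properties come from the moment-matched ellipse of the binary
  footprint (per hemisphere), orientation in degrees in (−90, 90] against
  the first image axis. An empty footprint is recorded as zeros with a flag
  so every subject keeps a 55-length vector.
- N for the projections defaults to the full hemisphere ROI size (the least
  arbitrary choice: the projection is then the ROI footprint); a count or
  fraction can be configured.
- Hemispheres come from atlas labels (1 = left, 2 = right by default), with
  a sagittal-midplane rule as fallback for single-label atlases.
- Coordinates are 0-based voxel indices; mm conversion is presentation-only.

The 55-element layout (9 means + 6 CoM + 30 projection properties + 10
counts) is the unique composition consistent with per-hemisphere
projections carrying five properties each; the canonical order is frozen in
`MORPH_FEATURE_NAMES`.

## Screening

"Welch's test" is the unequal-variance two-sample t-test with Satterthwaite
degrees of freedom, two-sided. No multiple-testing correction is applied —
the screen is descriptive and only decides whether a whole source is kept,
which is also why the source statistic is the *minimum* p over member
features. Missing values are handled pairwise-complete per feature; a
feature with fewer than two finite values in a class raises an error naming
the feature. Identical constant groups return (t=0, p=1).

## Ensemble

- Base learner: linear-kernel SVC, C = 1, features standardized per column
  with training-fold statistics only. A KNN learner (default k = 5) exists
  behind the same contract for comparison but is off by default, since
  linear maximum-margin classifiers dominate it on this kind of data.
- Support profiles (per-class supports summing to 1) are produced from the
  signed margin by logistic squashing — an implementation convention; a
  maximum-margin classifier has no canonical posterior.
- Windowed weights are used **unnormalized** in the vote: the argmax is
  scale-invariant, and the published example weights (0.90, 0.77, 0.14,
  0.10) do not sum to one. The exponential window's printed coefficients
  hit its boundary conditions only to ~1e−3; this is inherent to the
  printed constants, not to the implementation.
- Margin fusion ("hyperplane distance") is a documented convention: margins
  are divided by sᵢ, the median absolute training-fold margin of source i,
  making sources commensurable without test-set leakage, then summed with
  weight 1 per source.
- Ties (equal vote scores, zero margin sums) resolve to the first class in
  the configured ordering (HC) — deterministic and seed-independent.
- A fold in which every windowed weight is zero falls back to an unweighted
  majority vote, emits a warning, and is recorded in the result.
- Binary classification only (k = 2) is tested, though the vote machinery
  is written for general k.
- Leakage discipline: inner-loop accuracies, scalers, margin scales and
  models are all computed from training rows only; a dedicated test
  corrupts a held-out subject's features and asserts its fold's weights are
  bit-identical.

## Evaluation

- Metrics with zero denominators are NaN plus an `undefined` flag, never
  silently zero.
- The permutation test reruns the caller's full pipeline under permuted
  labels (weights are re-estimated under each permutation) and uses the
  +1-corrected empirical p = (1 + #{perm ≥ ref})/(n_perm + 1). The pipeline
  is called twice on the original labels to verify determinism before the
  null is built. At small subject and permutation counts, accuracy ties
  make the p-value distribution discretely conservative; the calibration
  test therefore asserts validity (no anti-conservative excess at any
  level) plus rough uniformity rather than exact uniformity.
- The one-sample t-test of the permuted mean against the reference reports
  its statistic signed, with a 95% CI of the permuted mean.
- ROC scores for fused predictions are the weighted vote margin (signed
  toward the patient class) or the scaled margin sum under margin fusion;
  AUC is trapezoidal and equals the tie-aware pairwise ranking probability.

## Problem sizes in the shipped tests

The stochastic suites use: 20 phantoms at 40×48×40 for normalization
closure; 20 cohorts of 16 subjects at 24×30×24 for the fusion-direction
comparison (quadratic windowing vs majority voting, matched seeds); 60 null
cohorts × 19 permutations for permutation calibration; 1000 null features
at n = 50 per class for the Welch type-I rate ([0.035, 0.065] band at the
0.05 level). These sizes are the package's choice of desk-scale study
conditions; all generators accept larger values.

## Known limitations

- No SPECT physics (scatter, attenuation, point-spread, Poisson counts) and
  no spatial registration: inputs are assumed co-registered on a common
  grid, and volumes are used in stored voxel space without reorientation.
- i.i.d. voxels and independent biomarker columns in the phantom — spatial
  and between-test correlation structure of real data is absent.
- Missing data are excluded subject-wise per experiment (complete-case);
  no imputation.
- The α-stable refinement fixes (α, β) at quantile estimates; studies that
  need efficient α estimates should fit externally and pass parameters in.
- Plot generation is out of scope; all quantities are emitted as JSON/CSV
  and plot trivially from there.
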