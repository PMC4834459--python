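# Methods

## Scope and design

The package implements a subject-level classification pipeline for
case–control fMRI: psychophysiological-interaction (PPI) contrast maps are
reduced to gray-matter feature vectors and classified with
maximum-uncertainty LDA (MLDA) under leave-one-subject-out cross-validation
(LOOCV). Because the clinical data this design targets are not publicly
available, a synthetic-data module generates cohorts with a known ground
truth; every empirical statement below is one the test suite or
`scripts/acceptance.py` computes at run time.

## Synthetic data

### PPI-like maps (`generate_ppi_maps`)

Each subject's map is Gaussian white noise smoothed with a separable
Gaussian kernel (σ_axis = FWHM / (2√(2 ln 2)) / voxel_size_axis, truncated
at 4σ, zero-padded boundaries — the standard neuroimaging convention) and
divided by the kernel's root sum-of-squares, so interior voxels have unit
marginal variance while the smoothing-induced spatial correlation is
retained. Patients additionally receive a mean shift of `effect_size_d` at
the truth voxels: ceil(`signal_fraction` × |mask|) voxels grown as ~4
contiguous 6-neighbourhood clusters from seeds placed at least one kernel
radius from the volume edge (where the variance normalisation is exact), so
the realised voxelwise Cohen's d matches `effect_size_d` up to sampling
error (verified at n = 100/group within ±0.3).

Defaults mirror the acquisition this emulates: TR 2.0 s, 400 volumes × 3
runs, 2.29×2.29×3 mm voxels, 6 mm FWHM, 25 patients / 21 controls, 1%
signal fraction. The test grid is 20×24×20 voxels rather than a full MNI
field of view; that keeps cohort generation and LOOCV at desk scale and is
the grid every calibration suite uses. `effect_size_d = 1.5` is the default
study condition: with ~50–60 correlated signal voxels it produces clearly
above-chance but imperfect classification, the regime the pipeline is meant
to probe; the real data's effect size is unknowable from published numbers.

### Event-related BOLD runs (`generate_timeseries_cohort`)

The generative model per voxel is
`y(t) = β₁ p(t) + β₂ s(t) + β₃ (s−s̄)(p−p̄)(t) + σ ε(t)` with
`p` the guilt-vs-indignation regressor, `s` the seed signal (HRF-convolved
all-trial regressor plus AR(1) noise), and ε stationary AR(1) noise
(ρ = 0.3 by default — the minimal temporally correlated noise model; no
scanner drift, motion or physiological noise is simulated). The interaction
coefficient β₃ is zero everywhere except the truth voxels, where controls
carry `beta_ppi_control = 0.5` and patients `beta_ppi_patient = 0`: a
guilt-selective absence of context-dependent seed coupling in patients.
Because groups differ only in β₃, the physiological contrast carries no
group information — the mechanism behind the condition-independent control
analysis sitting at chance. Seed-ROI voxels carry the seed signal plus
ordinary measurement noise.

Event schedules default to equal numbers of 5 s guilt / indignation /
baseline trials per run (30 each at the standard 800 s run length, reduced
proportionally on shorter test runs), in randomised order with jittered
inter-trial gaps; exact trial timings of the emulated paradigm are not
published, so the schedule is configurable.

## PPI GLM

The psychological regressor is built as a condition-weighted boxcar on a
0.1 s grid, convolved with a canonical double-gamma HRF (peak delay 6 s,
undershoot delay 16 s, unit dispersions, ratio 1:6, 32 s kernel), sampled at
volume onsets and mean-centered. The interaction column is the product of
the *mean-centered* seed series and psych regressor, centered per run; runs
are concatenated with per-run intercepts and no high-pass filtering by
default (confound columns can be supplied). The interaction is formed at
the BOLD level; neural-level deconvolution is deliberately omitted as
ill-posed, a documented divergence from deconvolution-based PPI
implementations. OLS is fit voxelwise; t = cᵀβ̂ / √(σ̂² cᵀ(XᵀX)⁻¹c) with
σ̂² = RSS/(n − rank X). Voxels with vanishing residual variance are flagged
rather than raised: t is signed infinity, or 0 when the contrast estimate is
itself zero. Type-I calibration on pure noise is verified at 1000 voxels
(5% ± 3·√(0.05·0.95/1000)).

Feature vectors order in-mask voxels by ascending linear index with x
varying fastest (Fortran ravel of the (x, y, z) array); the index table is
stored with every feature matrix so weight vectors back-project exactly.
Gray-matter masking is strict (> 0.25).

## MLDA

Pooled within-class covariance uses within-class centering with the
unbiased denominator n − 2. The shrinkage target is λ̄ = trace(Sp)/p (mean
over all p eigenvalues, structural zeros included); the alternative mean
over the nonzero spectrum is available as `lambda_bar_rule="nonzero"` and is
recorded in every report, since the "maximum entropy criterion" is loosely
specified in the literature this follows. S\*⁻¹ is applied through the
spectral identity S\*⁻¹ = (1/λ̄)(I − Φ_rΦ_rᵀ) + Φ_r diag(1/λᵢ\*) Φ_rᵀ using
the SVD of the centered data (rank ≤ n − 2); equivalence with the dense
p×p definition is verified to 1e-8 over hundreds of random instances.
Feature selection takes the top ceil(fraction × p) voxels by |wⱼ| of a
full-feature fit (ties broken by ascending voxel index); univariate-|t|
ranking is available as a configuration. Selection is nested inside every
LOOCV fold — the paper-era convention often left this ambiguous, so the
choice is surfaced in report metadata. The decision threshold is fixed at
0 with b the midpoint of the projected class means; there is no tunable
hyperparameter besides the fraction.

A single-sample class is tolerated inside a fit (with n ≥ 3 overall) so the
minimal 2+2 LOOCV cohort remains well defined; a full cohort still requires
two subjects per class.

## Evaluation statistics

Patients are the positive class. The binomial test is an exact one-sided
upper-tail sum computed with big-integer rationals. AUC is the exact pair
statistic P(z_patient > z_control) + ½P(tie), checked to 1e-12 against
trapezoidal integration of the threshold-swept ROC. The Mann–Whitney
statistic W is the U of the first subgroup (rank sum − n₁(n₁+1)/2,
midranks for ties), with the raw rank sum also reported because software
conventions differ; p is exact by enumeration for tie-free n₁+n₂ ≤ 12,
otherwise normal with tie and continuity corrections. A chi-square test of
the 2×2 confusion table is reported under its own name; it is not a
substitute for the rank-based AUC inference.

## Numerical choices and degenerate inputs

Singular values below 1e-10 of the largest are treated as structural zeros;
designs are validated for full column rank at construction, with collinear
columns named in the error. Constant decision values yield AUC 0.5 with a
warning record. Sphere ROIs use voxel-center world-space distance
(≤ radius + 1e-9 to absorb affine round-off). NIfTI affines are snapped to
float32 on write (the NIfTI-1 header's precision) so write→read round-trips
are idempotent.

## Known limitations

- LOOCV accuracy on null data is overdispersed relative to an i.i.d.
  binomial: fold training sets share n−2 subjects and the fold-nested 1%
  selection is nearly identical across folds, so per-cohort null accuracy
  has roughly twice the binomial standard deviation and a slight
  below-chance mean (the leave-one-out class-imbalance effect). Simulation
  at these settings shows ~70–77% of null cohorts inside the central 95%
  binomial band. Permutation tests, not binomial bands, are the reliable
  null reference for this pipeline.
- Synthetic cohorts have stationary Gaussian statistics, a shared truth
  mask, and no anatomy, motion or physiological artifacts; passing
  calibration here demonstrates correctness of the machinery, not
  performance on real patient data.
- The simulator takes condition labels as given; post-scan rating-based
  trial labelling of the emulated paradigm is out of scope.
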