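# Methods

## Signal metrics

Every ROI time series is z-normalized (mean 0, SD 1, ddof = 1) before any
metric is computed; the same n − 1 divisor is used for the SD metric and for
the entropy tolerance scale, so with z-scored input r·SD reduces to r.

**MSSD** is Σ(xᵢ₊₁ − xᵢ)²/(n − 1): the divisor equals the number of
successive differences, so the statistic is the plain mean of squared
steps. It is invariant to additive shifts and, because the series is
z-scored first, to affine rescaling.

**Sample entropy** follows the canonical template-matching definition:
Chebyshev (max-norm) distance, self-matches excluded, pairs counted once
(i < j), and both the length-m count B and the length-(m + 1) count A taken
over the common n − m template start positions. When A = 0 or B = 0 the
conditional probability is undefined and the function returns a NaN
*failure marker* instead of raising, so that calibration can count failures.
A constant series returns exactly 0 (every pair matches at every length).
`sample_entropy_grid` evaluates a full (m, r) grid per series by computing
the pairwise template distances once per pattern length and resolving all
tolerances with one sort + binary search; it is exactly equal to the
per-cell scalar routine and is what makes dense calibration grids cheap.

## Entropy-parameter calibration

The tolerance r and pattern length m are free parameters of sample entropy;
the calibration procedure selects them using noise-reference (CSF) voxels,
where entropy estimates should be stable. Per subject and (m, r) cell the
dispersion statistic is

SE = 1.96 · (σ_SampEn / mean_SampEn)²,

with σ and the mean taken across that subject's voxels (the per-participant
reading: the median of SE is then taken across participants, which would be
vacuous if voxels were pooled). The squared form is implemented as printed
in the source procedure even though it is dimensionally unusual (1.96 times
a squared coefficient of variation); the unsquared variant is available via
`squared=False`. A cell is acceptable iff median SE < 0.1 (configurable)
and the failure count, summed over *all* voxels and subjects, is zero. A
zero mean voxel entropy makes SE undefined and the cell unacceptable — a
degenerate reference signal carries no calibration information.

Grey-matter entropy is averaged over the selected conditions cell-wise;
failed cells are excluded pairwise from their own mean (with a logged
count) rather than dropping the subject, preserving sample size. The
shipped default selection is m = 2 with r ∈ {0.25 … 0.65}: the acceptable
m = 2 conditions minus r = 0.20, which contrasts with the other m = 2
tolerances; the exclusion list is configuration, not a rule.

## Structural networks

Weights are nonnegative with zero diagonal; a binary anatomical-presence
mask zeroes undocumented connections before anything else. Because
probabilistic tractography output can be asymmetric, matrices are
symmetrized by the arithmetic mean of (i, j) and (j, i) by default
(`symmetrize=False` keeps the directed graph) — global efficiency is used
here as an undirected summary and no convention is imposed by the weights
themselves. Edge length is 1/weight, shortest paths are computed by
Dijkstra (scipy.sparse.csgraph), and disconnected pairs contribute 0
(1/∞ := 0). Head motion is removed from per-subject GE by OLS on
[1, FD], with the grand mean added back: downstream PLS is
translation-insensitive, so the mean restoration is purely cosmetic.

## Partial least squares

*Mean-centering PLS*: SVD of the groups × variables matrix of group means
after removing each column's grand mean across group means (grand-mean
removal is the default; group-wise variants can be built by pre-centering
the input). *Behavioral PLS*: within each group, brain and behavior columns
are z-normalized and the behavior × brain Pearson correlation matrix is
formed; group blocks are stacked row-wise and decomposed by SVD. Covariance
explained per LV is its squared singular value over the sum.

Numerical conventions:

- **Sign fixing**: the largest-|value| element of each brain salience is
  made positive; SVD signs are otherwise arbitrary, and this makes repeated
  fits bit-identical.
- **Permutation test**: subject rows of the brain block are reshuffled
  across the whole sample (breaking both group and behavior linkage) and
  singular values recomputed; p per LV is (count + 1)/(n_perm + 1), so p is
  never exactly 0 (the plain proportion is available with
  `smoothed=False`). Default 1000 permutations.
- **Bootstrap**: resampling with replacement is stratified within group
  (group sizes preserved); each bootstrap solution is aligned to the
  original by Procrustes rotation of the brain-salience block (the rotation
  is applied to both blocks; per-LV sign matching is available with
  `procrustes=False`). BSR = original salience / SD of aligned bootstrap
  saliences; |BSR| ≥ 2 flags a reliable variable. Percentile 95% CIs are
  reported for the design/behavior saliences. Degenerate resamples
  (zero-variance column) are redrawn, up to 100 consecutive retries.
  Default 500 samples.
- Behavior collinearity: pairwise behavior correlations with |r| > 0.8 are
  logged as warnings, since strongly overlapping predictors bias the
  decomposition; the caller decides what to drop.

## Univariate statistics

Pooled-variance two-sample t (identical from raw vectors or their n/mean/SD
summaries), Pearson chi-square without continuity correction, Pearson r
with t-based p on n − 2 df, Fisher r-to-z comparison of independent
correlations, and the variance-ratio F on (n₁ − 1, n₂ − 1) df; all p-values
two-sided. The shipped cohort summary table reproduces the published
group-difference t-values, the handedness chi-square and the Fisher Z
comparisons to 2 decimal places. The published behavior-score F values
(2.29 and 3.64 on df 19, 16) are *not* the simple squared ratios of the
accompanying printed SDs (1.18²/0.94² = 1.576; 1.23²/0.93² = 1.749); the
test actually behind those numbers is not identifiable from the report.
The standard ratio is implemented and the discrepancy is documented here
rather than reconciled.

## Synthetic data

The generator's purpose is to emulate the *statistical structure* the
analysis assumes, not BOLD physiology. Defaults: two groups of 20 and 17
subjects, 82 ROIs, 180 time points (the modelled acquisition length), AR(1)
coefficients in [0.1, 0.8], 25 CSF voxels per subject, structural edge
density 0.3, effect size 1.0 with behavior noise SD 0.5 (a moderate planted
effect; the recovery analyses use noise SD 0.25–0.3 as the strong-effect
condition).

A per-subject latent trait u ~ Uniform(−1, 1) drives everything that should
covary: 20 "planted" ROIs use φ = mid − half·u (higher trait → lower φ →
higher MSSD and entropy), the structural-weight scale is exp(0.3·u) (GE
increases with the trait), and behavior columns are sign·effect·z(X·w) +
noise with w the unit-norm planted salience (efficiency, age and IQ load
positively; severity negatively; FD is independent noise). Non-planted ROIs
draw φ independently per subject and ROI, keeping their metric columns
approximately uncorrelated so that recovered saliences can be compared
against the planted pattern. CSF voxels are iid standard normal — white
noise is the entropy-stable reference the calibration assumes.

AR(1) was chosen as the minimal process with a tunable
variability/complexity ordering and an analytic oracle: a unit-variance
AR(1) has population MSSD 2(1 − φ). Note that z-normalizing a *finite*
autocorrelated series deflates its sample variance, biasing MSSD upward by
O(φ/T) (≈ +0.04 at φ = 0.9, T = 180); Monte-Carlo agreement with the closed
form is therefore asserted within 3 MC standard errors plus an 8φ/T
allowance. What the simulations do **not** model: hemodynamics, spatial
autocorrelation, motion artifacts beyond an FD covariate, scanner drift, or
realistic connectome topology — passing tests demonstrate correctness of
the estimators and inference machinery under the assumed structure, not
performance on real fMRI.

## Problem sizes and determinism

The shipped analyses use the full 4 × 16 calibration grid, 1000
permutations and 500 bootstrap samples at the default study size (37
subjects × 82 ROIs × 180 time points), which completes in well under a
minute; the type-I-error simulation uses 200 replicates at 200 permutations
each. All randomness flows through `numpy.random.default_rng` seeded from a
single base seed with fixed substream offsets; identical config + seed
reproduces every output byte-for-byte (no timestamps are written into
result files).

## Known limitations

- Sample entropy is single-scale; multiscale variants are out of scope.
- The grid routine holds all O((n − m)²/2) template distances in memory —
  fine for n in the hundreds, not for very long recordings.
- Behavioral PLS requires complete cases; entropy estimation failures in
  grey matter must be resolved (by condition averaging) before fitting.
- The permutation scheme treats subjects as exchangeable across groups;
  within-group permutation is available but not the default.
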