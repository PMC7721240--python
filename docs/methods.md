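# Methods

This note documents the models, conventions and numerical choices behind
`nbstab`, and what the synthetic experiments do and do not demonstrate.

## Data model and voxel ordering

All analyses operate on a cohort `(X, y, C)`: `X` is participants ×
masked-voxels (one contrast image per participant), `y` a behavioral score
(task accuracy, proportion correct), `C` the nuisance covariates age (years)
and mean frame displacement (mm). Statistical maps are vectors over the
in-mask voxels in a single fixed order — ascending linear index with the
first axis fastest (Fortran ravel) — which is a property of the mask alone;
every map computed against the same mask shares it. Writing a map back to a
3D NIfTI volume fills out-of-mask voxels with NaN so that thresholding a
written map can never recruit voxels outside the analysis mask. Volumes are
written as single-file NIfTI-1, float32.

At cohort assembly from disk, any voxel that is NaN in at least one
participant's volume (low-signal voxels in real first-level outputs) is
removed from the analysis mask; inside the mask the data are NaN-free by
construction.

## Synthetic cohort generator

The generator's purpose is to provide cohorts whose *population* structure
is known exactly, so estimator behavior can be measured against ground
truth.

**Covariates and behavior.** (age, FD, behavior-latent) are drawn jointly
as correlated Gaussians: independent standard normals multiplied by the
Cholesky factor of a target 3×3 correlation matrix, then scaled to the
marginal means/SDs. Two presets encode the two study designs the package
emulates:

| preset | n | corr(age,FD) | corr(age,acc) | corr(FD,acc) | age | FD | strata |
|---|---|---|---|---|---|---|---|
| `dallas_like` | 171 | +0.46 | −0.48 | −0.29 | 53.03 ± 19.13 | 0.25 ± 0.08 mm | 4 age groups |
| `hcp_like` | 865 | +0.12 | −0.09 | −0.19 | 28.72 ± 3.74 | 0.15 ± 0.06 mm | none |

The behavioral score is `clip(0.78 + 0.08·z, 0, 1)` with `z` the behavior
latent; FD is floored at 0. The FD and behavior marginals are package
choices (plausible values for a lifespan working-memory cohort and a young
adult cohort; accuracy averaged over hard task conditions sits well below
ceiling). They were chosen so the truncations are negligible: measured at
n = 10⁶, clipping changes the achieved correlations by < 0.001, far inside
the ±0.01 recovery tolerance the tests enforce.

**Brain–behavior truth.** A truth map assigns each voxel a target
population correlation ρ_v with the behavioral latent. Three named
patterns: `localized_strong` (a sphere, default radius 3 voxels, at
ρ = 0.5, at the grid center), `diffuse_weak` (a random 30% of voxels at
ρ = 0.15, selection seeded), and `null`. Voxel data are generated as

    X_iv = ρ_v · z_i + √(1 − ρ_v²) · ε_iv ,   ε_iv ~ N(0, 1) i.i.d.

so `corr(X_v, z) = ρ_v` exactly in the population. The correlation is
embedded against the pre-clipping latent rather than the clipped score —
an exact construction whose clipping distortion is *measured* (above), not
assumed away. Covariates do not load on voxels by default (the truth is a
pure brain–behavior correlation); an optional per-voxel age-loading term
exists to exercise residualization.

**Strata.** The lifespan design uses four age groups (20–35, 36–55, 56–69,
70–94). By default strata are assigned by the *sample's* age quartiles,
which guarantees 42–43 members per group at n = 171 and therefore makes
every stratified schedule entry feasible for every seed; with the fixed
group bounds and a Gaussian age marginal, the youngest group's expected
size (~31) sits at the feasibility edge of the 12×10 entry (needs 30) and
random seeds would fail infeasibly often. Fixed-bound assignment remains
available (`assign_age_strata(..., method="bounds")`) for data whose age
distribution matches the bounds.

**Default grid.** 20×20×20 voxels at 3 mm isotropic (8,000 voxels) — small
enough for desk-scale loops, large enough for spatial-overlap statistics.
Tests and examples use 6³–16³ grids to keep the default suite fast; the
stated problem sizes for each experiment are in the tests themselves.

**Not modeled.** Spatial autocorrelation (smoothness) of the noise, time
series/HRFs, site effects. Voxel noise is independent across voxels, which
matters for interpretation (below).

## Subsampling

All subsamples of one size are pairwise disjoint (drawn without replacement
across subsamples); draws at different sizes are fresh, so participants
recur across sizes. Stratified draws put exactly `size / n_strata` members
of each stratum into every subsample and require divisibility (every
lifespan-design size is a multiple of 4); an explicit error is preferred to
silent imbalance. RNG streams are derived per size from the master seed
(`SeedSequence([seed, size])`), so adding or removing a size from a
schedule never changes the draw at another size. Within-stratum selection
is uniform at random.

## Univariate arm

Age and FD are residualized from `y` and from every voxel column by OLS
against [intercept, age, FD]; correlating the residuals equals the partial
correlation (verified against the closed-form partial-correlation oracle in
the tests). The correlation map is converted to t with `df = n − 2 − q`,
q = 2, matching a second-level regression with behavior + age + FD +
intercept. Residualization is computed **within each subsample** by default
(each subsample is its own analysis sample); cohort-level residualization is
a config switch.

Numerical conventions: zero-variance voxels get r = 0 plus a flag (never
NaN, so similarity metrics cannot propagate NaN; flagged voxels are excluded
from thresholded sets); |r| = 1 maps to a ±1e6 t sentinel; thresholding is
inclusive (≥). The one-sample task-effect map (`group_ttest`) uses df = n−1
with the same sentinel convention.

## Behavioral PLS

Closed form as in the README; the equivalence with a general SVD of the
1 × voxels correlation matrix is asserted at 1e-10 on random instances.
Conventions that were genuinely open, fixed and documented here:

- **Brain scores** are computed on the column-standardized `X` so scores
  are comparable across subsamples; for a fixed sample the correlation with
  `y` is unaffected by this choice.
- **Permutation test** permutes `y` rows (equivalent to permuting rows of
  `X`), recomputes the singular value, and uses add-one smoothing
  `p = (1 + b)/(1 + P)` so p is never 0. Ties with the observed singular
  value count toward b; a 1e-9 relative tolerance prevents floating-point
  noise from dropping exact ties (at small n the identity permutation
  recurs and *must* tie). Residualization is applied once, upstream, to
  both `X` and `y`; it is not recomputed inside the permutation loop.
- **BSR** divides the observed *unnormalized* correlation vector by the
  bootstrap SD of the per-replicate correlation vectors, each sign-aligned
  to the observed one (the single-LV case of procrustes alignment). Using
  the unnormalized vector decouples the ratio from the singular value and
  matches "salience / SE" up to a common constant. Zero-SD voxels get
  BSR = 0 with a flag; replicates with constant resampled `y` are redrawn
  (at most 10 times). Permutation and bootstrap use separate substreams of
  the seed.

## Similarity metrics

Spearman ρ is computed over **all** masked voxels of the unthresholded
maps (average ranks for ties; constant maps are an error). Jaccard uses the
positive tail at threshold 3 by default; an empty-union pair is defined as
Jaccard 0 with a `both_empty` flag in the pair table — "nothing replicated"
counts as zero stability. Penetration maps count suprathreshold membership
per voxel across the maps of one size, report counts ≥ 2 and apply no
clustering. For the PLS arm the thresholded/compared map is the BSR map;
for the univariate arm it is the t map. Dice is provided as a convenience
(`dice = 2J/(1+J)`).

The method comparison (`compare_methods`) computes per-size mean Jaccard
for both arms and a paired t test across sizes (df = n_sizes − 1).

## Pipeline determinism

A run is a pure function of (config, master seed): subsample draws, the
per-(size, subsample) PLS seeds, and all table orderings are derived
deterministically, and CSVs are written with a fixed float format, so
re-runs are byte-identical (asserted in the tests).

## What the synthetic experiments show — and what they don't

With the localized-strong truth the pipeline reproduces the qualitative
phenomena it was built to study: pairwise map similarity (ρ, Jaccard) rises
steeply with subsample size; the PLS brain-score–behavior correlation is
systematically inflated in small subsamples and declines monotonically
toward its population value; LV significance rates rise with n; and the
maximum-penetration voxels at large n coincide with the true support.

Two structural simplifications bound what the *magnitudes* mean. First,
voxel noise is spatially independent, so suprathreshold sets lack the
cluster structure of real maps and Jaccard values at a given n are not
directly comparable to real-data values. Second, the generator embeds a
single common behavioral factor: the optimal whole-brain combination of
~100 signal voxels then has a population brain-score correlation near 1,
so the winner's-curse decline, while strictly monotone and highly
reproducible, spans a narrower numeric range than in real data where
idiosyncratic structure caps the attainable correlation much lower. The
tests therefore assert directions, orderings and calibrations (type-I rate
of the permutation test on null cohorts, exactness against enumeration,
oracle equivalences), not real-data effect sizes.

## Known limitations

- Single behavioral variable (single LV); no multi-condition or multi-group
  PLS, and no block-level task-contrast PLS — the task-effect surrogate is
  a one-sample t map over contrast images.
- No FWE/random-field or cluster-extent inference; the fixed threshold 3 is
  the similarity-analysis convention, not a corrected significance level.
- No resampling between grids; inputs must share one grid.
- Freedman–Lane-style recomputation of the residualization per permutation
  is a noted alternative, not implemented.
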