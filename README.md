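# nbstab — sample-size stability of voxelwise brain–behavior correlations

How many participants does a task-fMRI study need before the map of
brain–behavior correlations it produces is *stable* — before an independent
sample of the same size would find roughly the same voxels? `nbstab` is a
library for answering that question by experiment: it draws multiple
**disjoint subsamples** of graded sizes from a cohort of per-participant
contrast images, computes a brain–behavior correlation map in each subsample
with both a univariate and a multivariate (behavioral PLS) approach, and
quantifies cross-subsample agreement. It is aimed at methods researchers and
at anyone planning an individual-differences fMRI study who wants to
simulate the stability they can expect at a given n.

Because real cohorts of hundreds of participants are not needed to study the
*behavior of the estimators*, the package ships a synthetic cohort generator
with known ground truth: per-participant contrast volumes `X` (participants
× voxels), a behavioral score `y` (task accuracy), and nuisance covariates
(age, mean frame displacement) with a realistic correlation structure.
Real data can be ingested instead (one NIfTI contrast volume per
participant, a binary mask, and a participants CSV).

## The statistics at the core

For each subsample, after residualizing age and FD from `y` and from every
voxel of `X`:

- **Univariate arm** — per-voxel Pearson correlation
  `r_v = corr(X_v, y)`, converted to `t_v = r_v √(df / (1 − r_v²))` with
  `df = n − 2 − q` (q = 2 nuisance covariates).
- **Behavioral PLS arm** — with a single behavioral variable, the SVD of the
  1 × voxels correlation matrix is available in closed form: singular value
  `s = ‖r‖₂`, unit-norm voxel **salience** `u = r / ‖r‖₂`. Brain scores are
  the projection of the column-standardized `X` onto `u`; their correlation
  with `y` summarizes the whole-brain effect. LV significance comes from a
  permutation test on `s` (default 1,000 permutations,
  `p = (1 + #{s* ≥ s}) / (1 + P)`), and voxel robustness from the
  **bootstrap ratio** `BSR_v = r_v / SE_boot(r_v)` (default 1,000
  resamples), read like a z score.
- **Stability metrics** — for every pair of maps at one subsample size:
  Spearman ρ over all unthresholded masked voxels, and the Jaccard index
  (intersection over union) of the suprathreshold voxel sets (threshold 3,
  positive tail). **Penetration maps** count, per voxel, how many of the
  thresholded maps at a size include it (reported from 2 overlaps upward,
  no clustering).

Two built-in designs mirror a lifespan working-memory cohort (n = 171, four
age strata, subsample schedule 12×10, 24×7, 36×4, 48×3, 60×2, 72×2, 84×2,
draws balanced across age groups) and a large young-adult cohort (n = 865,
schedule 20–420). All subsamples of one size are pairwise disjoint.

## Worked example

`examples/stability_curves.py` runs the full pipeline on a synthetic
280-participant cohort with a strong localized effect (a sphere of voxels
with population correlation ρ = 0.5 to behavior):

```text
similarity by size (rho on unthresholded maps, Jaccard at threshold 3):
 size     method  mean_rho  mean_jaccard  mean_overlap
   12        pls     0.187         0.125        17.357
   12 univariate     0.192         0.063         3.679
   24        pls     0.264         0.268        32.667
   24 univariate     0.268         0.158        10.533
   48        pls     0.311         0.555        71.833
   48 univariate     0.313         0.490        56.833
   96        pls     0.332         0.932       123.000
   96 univariate     0.330         0.937       118.000

PLS by size (means over subsamples):
      r_brainscore  perm_p
size
12           0.997   0.005
24           0.994   0.005
48           0.991   0.005
96           0.988   0.005
```

Reading the numbers: map agreement grows steeply with sample size — at
n = 12 two disjoint subsamples share only ~6–12% of their suprathreshold
voxels (Jaccard), at n = 96 over 90% — while the PLS brain-score–behavior
correlation moves the *opposite* way, largest in the smallest samples.
That is the winner's curse: a latent variable fit to a small sample
overstates how well the brain pattern tracks behavior. The `mean_overlap`
column converges on 123, the true number of signal voxels. The other
examples (`simulate_cohort.py`, `behavioral_pls_demo.py`) demonstrate the
generator's parameter recovery and a single PLS fit with permutation and
bootstrap inference.

A thin CLI wraps the same functions:

```bash
nbstab simulate --preset dallas_like --out cohort_dir
nbstab run --config experiment.yaml --seed 1 --out results_dir
nbstab report --config results_dir/config_used.yaml --out rendered
```

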