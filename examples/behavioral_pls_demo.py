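"""Behavioral PLS on a single analysis sample.

Simulates a 48-participant sample with a localized effect, residualizes age
and mean FD from both the behavior and every voxel, and runs the
single-latent-variable behavioral PLS: salience map, permutation p for the
LV, and the bootstrap-ratio (BSR) map, interpreted like a z map.
"""

import numpy as np

from nbstab import (
    DALLAS_COVARIATES,
    VolumeGrid,
    make_truth,
    residualize,
    run_behavioral_pls,
    simulate_cohort,
)

truth = make_truth("localized_strong", VolumeGrid.isotropic((10, 10, 10)))
cohort = simulate_cohort(48, truth, DALLAS_COVARIATES, seed=3)

X = residualize(cohort.X, cohort.C)  # per-voxel nuisance removal
y = residualize(cohort.y, cohort.C)

res = run_behavioral_pls(X, y, n_perm=1000, n_boot=1000, seed=3)
support = cohort.truth_vector() != 0

print(f"singular value:              {res.singular_value:.3f}")
print(f"brain score-behavior r:      {res.r_brainscore_behavior:.3f} "
      f"(inflated at n = 48: the LV is fit to this sample)")
print(f"LV permutation p:            {res.perm_p:.4f}  ({res.n_perm} permutations)")
print(f"voxels with BSR >= 3:        {(res.bsr >= 3).sum()} of {res.bsr.size}")
print(f"  ... inside the true support: {((res.bsr >= 3) & support).sum()} "
      f"(support has {support.sum()} voxels)")
print(f"mean |BSR| at null voxels:   {np.abs(res.bsr[~support]).mean():.2f}")
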