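"""Synthetic cohort generator with known brain-behavior ground truth.

Generates cohorts of per-participant contrast "volumes" (one image per
person), a behavioral score (task accuracy, proportion correct) and two
nuisance covariates (age in years, mean frame displacement in mm), with

* a target per-voxel population correlation between contrast value and
  behavior (the *truth map*), embedded exactly against the pre-clipping
  behavioral latent, and
* a target 3x3 correlation structure among (age, FD, behavior), imposed by
  a Cholesky factor on independent standard normals.

Two named condition presets emulate the two study designs this package is
built around: a lifespan working-memory cohort ("dallas_like", n=171, four
age strata, strong covariate confounding) and a young-adult cohort
("hcp_like", n=865, no strata, weak confounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .volume_io import (
    CohortTable,
    VolumeGrid,
    VoxelMask,
    devectorize,
    load_volume,
    read_cohort_table,
    save_volume,
    vectorize,
)

__all__ = [
    "TruthSpec",
    "CovariateStructure",
    "Cohort",
    "make_truth",
    "simulate_cohort",
    "make_preset_cohort",
    "write_cohort",
    "read_cohort",
    "assign_age_strata",
    "DALLAS_COVARIATES",
    "HCP_COVARIATES",
    "DEFAULT_GRID_SHAPE",
    "AGE_GROUP_BOUNDS",
]

#: Default synthetic grid: 20x20x20 voxels at 3 mm isotropic (~8,000 voxels).
DEFAULT_GRID_SHAPE: tuple[int, int, int] = (20, 20, 20)

#: Age-group bounds of the lifespan design: 20-35, 36-55, 56-69, 70-94 years.
AGE_GROUP_BOUNDS: tuple[float, ...] = (35.5, 55.5, 69.5)
AGE_GROUP_LABELS: tuple[str, ...] = ("20-35", "36-55", "56-69", "70-94")


@dataclass(frozen=True)
class TruthSpec:
    """Per-voxel target population correlation between brain and behavior."""

    grid: VolumeGrid
    rho_map: np.ndarray  # 3D, shape == grid.shape
    pattern_kind: str = "custom"

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho_map, dtype=float)
        if rho.shape != self.grid.shape:
            raise ValueError("rho_map shape must match grid shape")
        if np.any(np.abs(rho) >= 1.0):
            raise ValueError("|rho| must be < 1 everywhere")
        rho = rho.copy()
        rho.setflags(write=False)
        object.__setattr__(self, "rho_map", rho)

    @property
    def support(self) -> np.ndarray:
        """Boolean 3D array marking voxels with nonzero target correlation."""
        return self.rho_map != 0.0


@dataclass(frozen=True)
class CovariateStructure:
    """Target correlations and marginals for (age, FD, behavior).

    ``corr`` is ordered (age, FD, behavior); it must be symmetric with unit
    diagonal and positive semi-definite. Behavior is clipped to
    ``behavior_clip`` after the affine transform (accuracy is a proportion);
    FD is floored at zero. Marginals are chosen so those truncations are
    negligible (measured, see the methods note).
    """

    corr: np.ndarray
    age_mean: float = 53.03
    age_sd: float = 19.13
    fd_mean: float = 0.25
    fd_sd: float = 0.08
    behavior_mean: float = 0.78
    behavior_sd: float = 0.08
    behavior_clip: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        corr = np.asarray(self.corr, dtype=float)
        if corr.shape != (3, 3):
            raise ValueError("corr must be 3x3, ordered (age, FD, behavior)")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("corr must have unit diagonal")
        eigmin = np.linalg.eigvalsh(corr).min()
        if eigmin < -1e-10:
            raise ValueError(f"corr is not positive semi-definite (min eig {eigmin:.3g})")
        corr = corr.copy()
        corr.setflags(write=False)
        object.__setattr__(self, "corr", corr)

    def cholesky(self) -> np.ndarray:
        # tiny jitter only if exactly singular
        try:
            return np.linalg.cholesky(self.corr)
        except np.linalg.LinAlgError:
            return np.linalg.cholesky(self.corr + 1e-10 * np.eye(3))


#: Lifespan working-memory design: age-FD 0.46, age-accuracy -0.48, FD-accuracy -0.29.
DALLAS_COVARIATES = CovariateStructure(
    corr=np.array([[1.0, 0.46, -0.48], [0.46, 1.0, -0.29], [-0.48, -0.29, 1.0]]),
    age_mean=53.03,
    age_sd=19.13,
    fd_mean=0.25,
    fd_sd=0.08,
)

#: Young-adult design: age-FD 0.12, age-accuracy -0.09, FD-accuracy -0.19.
HCP_COVARIATES = CovariateStructure(
    corr=np.array([[1.0, 0.12, -0.09], [0.12, 1.0, -0.19], [-0.09, -0.19, 1.0]]),
    age_mean=28.72,
    age_sd=3.74,
    fd_mean=0.15,
    fd_sd=0.06,
)


@dataclass
class Cohort:
    """A cohort ready for analysis.

    X is participants x masked-voxels (the fixed voxel order of ``mask``),
    y the behavioral score, C the (age, FD) covariate matrix.
    """

    X: np.ndarray
    y: np.ndarray
    C: np.ndarray
    mask: VoxelMask
    ids: list[str]
    strata: np.ndarray | None = None
    truth: TruthSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = self.X.shape[0]
        if self.X.ndim != 2 or self.X.shape[1] != self.mask.n_voxels:
            raise ValueError("X must be participants x mask.n_voxels")
        if self.y.shape != (n,) or self.C.shape[0] != n or len(self.ids) != n:
            raise ValueError("row counts of X, y, C, ids disagree")
        if self.strata is not None and np.asarray(self.strata).shape != (n,):
            raise ValueError("strata length must match participant count")
        if np.isnan(self.X).any():
            raise ValueError("X contains NaN inside the analysis mask")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def table(self) -> CohortTable:
        return CohortTable(
            ids=self.ids,
            behavior=self.y,
            covariates=pd.DataFrame(self.C, columns=["age", "fd"]),
            strata=self.strata,
        )

    def truth_vector(self) -> np.ndarray | None:
        """Truth rho over the analysis mask, in the fixed voxel order."""
        if self.truth is None:
            return None
        return vectorize(np.asarray(self.truth.rho_map), self.mask)


def make_truth(
    pattern_kind: str,
    grid: VolumeGrid | None = None,
    *,
    rho_strong: float = 0.5,
    rho_weak: float = 0.15,
    support_radius_vox: int = 3,
    diffuse_fraction: float = 0.3,
    center: tuple[int, int, int] | None = None,
    seed: int = 0,
) -> TruthSpec:
    """Build a truth map for one of the named brain-behavior patterns.

    ``localized_strong`` places a compact sphere (default radius 3 voxels)
    of correlation ``rho_strong`` at the grid center; ``diffuse_weak``
    scatters ``rho_weak`` over a random ``diffuse_fraction`` of voxels
    (selection seeded, hence reproducible); ``null`` is identically zero.
    """
    if grid is None:
        grid = VolumeGrid.isotropic(DEFAULT_GRID_SHAPE)
    for name, rho in (("rho_strong", rho_strong), ("rho_weak", rho_weak)):
        if not -1.0 < rho < 1.0:
            raise ValueError(f"{name} must lie in (-1, 1), got {rho}")
    shape = grid.shape
    rho_map = np.zeros(shape, dtype=float)
    if pattern_kind == "null":
        pass
    elif pattern_kind == "localized_strong":
        if support_radius_vox < 0:
            raise ValueError("support_radius_vox must be >= 0")
        if support_radius_vox > min(shape):
            raise ValueError("spherical support larger than the grid")
        c = center if center is not None else tuple(s // 2 for s in shape)
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        dist2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
        rho_map[dist2 <= support_radius_vox**2] = rho_strong
    elif pattern_kind == "diffuse_weak":
        if not 0.0 <= diffuse_fraction <= 1.0:
            raise ValueError("diffuse_fraction must lie in [0, 1]")
        n_vox = int(np.prod(shape))
        n_support = int(round(diffuse_fraction * n_vox))
        rng = np.random.default_rng(seed)
        chosen = rng.choice(n_vox, size=n_support, replace=False)
        flat = rho_map.ravel(order="F")
        flat[chosen] = rho_weak
        rho_map = flat.reshape(shape, order="F")
    else:
        raise ValueError(f"unknown pattern_kind {pattern_kind!r}")
    return TruthSpec(grid=grid, rho_map=rho_map, pattern_kind=pattern_kind)


def assign_age_strata(age: np.ndarray, method: str = "quantile") -> np.ndarray:
    """Assign the four lifespan age-group labels from simulated ages.

    ``quantile`` splits the sample at its age quartiles (groups of near-equal
    size, so every stratified schedule of the lifespan design is feasible);
    ``bounds`` uses the fixed group edges 35.5/55.5/69.5 years.
    """
    age = np.asarray(age, dtype=float)
    if method == "bounds":
        idx = np.digitize(age, AGE_GROUP_BOUNDS)
    elif method == "quantile":
        order = np.argsort(age, kind="stable")
        idx = np.empty(age.size, dtype=int)
        # near-equal group sizes: remainder spread over the youngest groups
        sizes = np.full(4, age.size // 4)
        sizes[: age.size % 4] += 1
        idx[order] = np.repeat(np.arange(4), sizes)
    else:
        raise ValueError(f"unknown stratum assignment method {method!r}")
    return np.asarray(AGE_GROUP_LABELS)[idx]


def simulate_cohort(
    n: int,
    truth: TruthSpec,
    cov: CovariateStructure = DALLAS_COVARIATES,
    seed: int = 0,
    *,
    strata: bool = False,
    stratum_method: str = "quantile",
    age_loading: float = 0.0,
) -> Cohort:
    """Draw a cohort with the given truth and covariate structure.

    (age, FD, behavior-latent) are drawn jointly with the target correlation
    matrix via its Cholesky factor, then scaled to the stated marginals; the
    recorded behavior is the clipped affine transform of the latent. Per
    voxel v, ``X[i, v] = rho_v * z_i + sqrt(1 - rho_v^2) * eps[i, v]`` with z
    the standardized behavioral latent, so the population correlation of
    X_v with the latent is rho_v exactly. ``age_loading``, if nonzero, adds
    that multiple of standardized age to every voxel (a confound term for
    exercising residualization; off by default).
    """
    if n < 4:
        raise ValueError("need at least 4 participants")
    rng = np.random.default_rng(seed)
    L = cov.cholesky()
    latent = rng.standard_normal((n, 3)) @ L.T  # columns: age, FD, behavior
    age = cov.age_mean + cov.age_sd * latent[:, 0]
    fd = np.maximum(cov.fd_mean + cov.fd_sd * latent[:, 1], 0.0)
    z = latent[:, 2]
    y = np.clip(
        cov.behavior_mean + cov.behavior_sd * z, cov.behavior_clip[0], cov.behavior_clip[1]
    )

    mask = VoxelMask(grid=truth.grid, in_mask=np.ones(truth.grid.shape, dtype=bool))
    rho = vectorize(np.asarray(truth.rho_map), mask)
    eps = rng.standard_normal((n, mask.n_voxels))
    X = z[:, None] * rho[None, :] + np.sqrt(1.0 - rho**2)[None, :] * eps
    if age_loading != 0.0:
        X = X + age_loading * ((age - age.mean()) / age.std())[:, None]

    stratum_labels = assign_age_strata(age, method=stratum_method) if strata else None
    ids = [f"sub-{i + 1:04d}" for i in range(n)]
    C = np.column_stack([age, fd])
    return Cohort(
        X=X, y=y, C=C, mask=mask, ids=ids, strata=stratum_labels, truth=truth, seed=seed
    )


def make_preset_cohort(
    preset: str,
    seed: int = 0,
    *,
    pattern_kind: str = "localized_strong",
    grid: VolumeGrid | None = None,
    n: int | None = None,
    **truth_params,
) -> Cohort:
    """Named study-design presets.

    ``dallas_like``: n=171, four age strata, lifespan covariate structure.
    ``hcp_like``: n=865, no strata, young-adult covariate structure.
    """
    if preset == "dallas_like":
        cov, n_default, strata = DALLAS_COVARIATES, 171, True
    elif preset == "hcp_like":
        cov, n_default, strata = HCP_COVARIATES, 865, False
    else:
        raise ValueError(f"unknown preset {preset!r}")
    truth = make_truth(pattern_kind, grid, seed=seed, **truth_params)
    return simulate_cohort(
        n if n is not None else n_default, truth, cov, seed=seed, strata=strata
    )


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write a cohort to disk in re-ingestable form.

    Layout: ``sub-XXXX_contrast.nii.gz`` per participant, ``mask.nii.gz``,
    ``participants.csv``, ``truth_rho.nii.gz`` when ground truth is present,
    and ``config.yaml`` echoing generation metadata. Volumes are float32.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = cohort.mask.grid
    for i, pid in enumerate(cohort.ids):
        vol = devectorize(cohort.X[i], cohort.mask, fill=np.nan)
        save_volume(vol, grid, directory / f"{pid}_contrast.nii.gz")
    save_volume(cohort.mask.in_mask.astype(float), grid, directory / "mask.nii.gz")
    cohort.table().to_frame().to_csv(directory / "participants.csv", index=False)
    if cohort.truth is not None:
        save_volume(np.asarray(cohort.truth.rho_map), grid, directory / "truth_rho.nii.gz")
    meta = {
        "n": cohort.n,
        "seed": cohort.seed,
        "grid_shape": list(grid.shape),
        "voxel_size_mm": [float(v) for v in grid.voxel_size_mm],
        "n_voxels": cohort.mask.n_voxels,
        "pattern_kind": None if cohort.truth is None else cohort.truth.pattern_kind,
        "has_strata": cohort.strata is not None,
    }
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return directory


def read_cohort(directory: str | Path) -> Cohort:
    """Re-ingest a cohort directory (written by :func:`write_cohort` or
    assembled from real per-participant contrast images + mask + table).

    Voxels that are NaN in *any* participant's volume are removed from the
    analysis mask at assembly, mirroring removal of low-signal voxels.
    """
    directory = Path(directory)
    table = read_cohort_table(directory / "participants.csv")
    mask_data, grid = load_volume(directory / "mask.nii.gz")
    base_mask = VoxelMask(grid=grid, in_mask=mask_data > 0.5)
    rows = []
    for pid in table.ids:
        data, _ = load_volume(directory / f"{pid}_contrast.nii.gz", expected_grid=grid)
        rows.append(vectorize(data, base_mask))
    X = np.vstack(rows)
    good = ~np.isnan(X).any(axis=0)
    if not good.all():
        keep3d = devectorize(good.astype(float), base_mask, fill=0.0) > 0.5
        base_mask = VoxelMask(grid=grid, in_mask=keep3d)
        X = X[:, good]
    truth = None
    truth_path = directory / "truth_rho.nii.gz"
    if truth_path.exists():
        rho3d, _ = load_volume(truth_path, expected_grid=grid)
        truth = TruthSpec(grid=grid, rho_map=np.nan_to_num(rho3d), pattern_kind="custom")
    return Cohort(
        X=X,
        y=table.behavior,
        C=table.covariates.to_numpy(dtype=float),
        mask=base_mask,
        ids=table.ids,
        strata=table.strata,
        truth=truth,
    )
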