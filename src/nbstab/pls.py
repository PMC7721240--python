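"""Behavioral partial least squares for one image per participant.

With a single behavioral variable the brain-behavior correlation structure
is the 1 x voxels vector r of voxelwise Pearson correlations, and its SVD
is available in closed form: the singular value is ||r||_2 and the (unit
norm) voxel salience is r / ||r||_2. Brain scores are the projection of the
column-standardized brain matrix onto the salience; their correlation with
behavior summarizes how well the whole-brain pattern tracks behavior.

Inference follows the usual resampling scheme: the latent variable's p-value
comes from permuting behavior across participants and comparing singular
values, and voxel robustness comes from a bootstrap ratio (BSR) - the
observed correlation divided by its bootstrap standard error - interpreted
like a z score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .univariate import _corr_columns

__all__ = [
    "PLSResult",
    "fit_pls",
    "permutation_pvalue",
    "bootstrap_bsr",
    "run_behavioral_pls",
]


@dataclass
class PLSResult:
    """Bundle of the fitted LV and its resampling inference."""

    salience: np.ndarray
    singular_value: float
    brain_scores: np.ndarray
    r_brainscore_behavior: float
    perm_p: float | None = None
    bsr: np.ndarray | None = None
    bsr_flags: np.ndarray | None = None
    n_perm: int = 0
    n_boot: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.salience = np.asarray(self.salience, dtype=float)
        nrm = np.linalg.norm(self.salience)
        if abs(nrm - 1.0) > 1e-10:
            raise ValueError(f"salience must be unit norm, got {nrm}")
        if self.singular_value < 0:
            raise ValueError("singular value must be nonnegative")
        if self.perm_p is not None and not (0.0 < self.perm_p <= 1.0):
            raise ValueError("perm_p must lie in (0, 1]")

    @property
    def n(self) -> int:
        return self.brain_scores.size


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    """Z-score each column; zero-variance columns become all-zero."""
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    return np.divide(Xc, sd, out=np.zeros_like(Xc), where=sd != 0.0)


def fit_pls(X: np.ndarray, y: np.ndarray) -> PLSResult:
    """Fit the single-LV behavioral PLS in closed form.

    Salience sign is oriented so the brain-score-behavior correlation is
    nonnegative. Raises if y is constant, fewer than 4 participants, or the
    correlation vector is identically zero (salience undefined).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 participants")
    r, _flags = _corr_columns(X, y)
    s = float(np.linalg.norm(r))
    if s == 0.0:
        raise ValueError(
            "all voxelwise correlations are zero; the salience direction is "
            "undefined (check for constant voxels or an unrelated behavior)"
        )
    salience = r / s
    scores = _standardize_columns(X) @ salience
    sc = scores - scores.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(sc) * np.linalg.norm(yc)
    r_bs = float(sc @ yc / denom) if denom > 0 else 0.0
    if r_bs < 0:  # orient the LV toward positive behavior correlation
        salience, scores, r_bs = -salience, -scores, -r_bs
    return PLSResult(
        salience=salience,
        singular_value=s,
        brain_scores=scores,
        r_brainscore_behavior=r_bs,
    )


def _perm_singular_values(
    X: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator, chunk: int = 512
) -> np.ndarray:
    """Singular values under row permutations of y, computed in batches."""
    Xz = _standardize_columns(np.asarray(X, dtype=float))
    n = Xz.shape[0]
    y = np.asarray(y, dtype=float)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        P = np.empty((b, n))
        for i in range(b):
            P[i] = y[rng.permutation(n)]
        Pc = P - P.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Pc, axis=1, keepdims=True)
        # constant permuted y cannot occur unless y itself is constant
        Pz = Pc / norms
        R = (Pz @ Xz) / np.sqrt(n)  # rows: correlation vectors (Xz has sd 1)
        out[done : done + b] = np.linalg.norm(R, axis=1)
        done += b
    return out


def permutation_pvalue(
    X: np.ndarray, y: np.ndarray, n_perm: int = 1000, seed: int | np.random.Generator = 0
) -> float:
    """Permutation p-value for the LV singular value.

    p = (1 + #{s_perm >= s_obs}) / (1 + n_perm); the add-one smoothing keeps
    p strictly positive (a raw proportion can return 0, which breaks
    log-scale reporting). Permutations that tie the observed singular value
    (e.g. the identity permutation, or tied y values) count as >=; a small
    relative tolerance keeps floating-point noise from dropping true ties.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0.0:
        raise ValueError("behavior vector is constant; permutation test undefined")
    s_obs = fit_pls(X, y).singular_value
    s_perm = _perm_singular_values(X, y, n_perm, rng)
    n_ge = int(np.sum(s_perm >= s_obs * (1.0 - 1e-9)))
    return float((1 + n_ge) / (1 + n_perm))


def bootstrap_bsr(
    X: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    max_retries: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap-ratio map: observed correlation / bootstrap SE.

    Participants are resampled with replacement jointly (rows of X with the
    matching entries of y). Each replicate's correlation vector is
    sign-aligned to the observed one (flip when the inner product is
    negative - the single-LV case of procrustes alignment), and the BSR is
    the observed, unnormalized correlation divided by the bootstrap SD.
    Returns (bsr, flags); flagged voxels had zero bootstrap SD and get 0.
    Replicates with constant resampled y are redrawn (max ``max_retries``).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    r_obs, _ = _corr_columns(X, y)
    boots = np.empty((n_boot, r_obs.size))
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if np.ptp(yb) > 0.0:
                break
        else:
            raise RuntimeError(
                f"bootstrap replicate kept drawing constant behavior after "
                f"{max_retries} retries (n = {n})"
            )
        rb, _ = _corr_columns(X[idx], yb)
        if rb @ r_obs < 0:
            rb = -rb
        boots[b] = rb
    sd = boots.std(axis=0, ddof=1)
    flags = sd == 0.0
    bsr = np.divide(r_obs, sd, out=np.zeros_like(r_obs), where=~flags)
    return bsr, flags


def run_behavioral_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> PLSResult:
    """Fit the LV and run both resampling procedures (defaults 1,000/1,000).

    Permutation and bootstrap use separate, deterministic substreams of the
    seed, so results are bit-identical across runs and changing one
    procedure's settings does not perturb the other.
    """
    ss_perm, ss_boot = np.random.SeedSequence(seed).spawn(2)
    res = fit_pls(X, y)
    perm_p = permutation_pvalue(X, y, n_perm, np.random.default_rng(ss_perm))
    bsr, flags = bootstrap_bsr(X, y, n_boot, np.random.default_rng(ss_boot))
    res.perm_p = perm_p
    res.bsr = bsr
    res.bsr_flags = flags
    res.n_perm = n_perm
    res.n_boot = n_boot
    res.seed = seed
    return res
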