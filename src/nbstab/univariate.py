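"""Univariate ("SPM-style") arm: residualization, voxelwise correlation and
t maps, one-sample task-effect maps, and map thresholding.

The second-level model is behavior + age + FD + intercept; residualizing
both the behavior and every voxel against [intercept, age, FD] and then
correlating gives the matching partial correlation, which is converted to a
t statistic with df = n - 2 - q (q nuisance covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import VoxelMask

__all__ = [
    "StatMap",
    "T_CAP",
    "residualize",
    "voxelwise_corr",
    "r_to_t",
    "group_ttest",
    "threshold_map",
]

#: Sentinel for infinite t (|r| = 1 or zero-variance one-sample test).
T_CAP = 1e6


@dataclass
class StatMap:
    """Per-voxel statistic values on the masked voxel vector.

    ``flags`` marks degenerate voxels (zero variance); they carry the value
    0 rather than NaN so similarity metrics never propagate NaN, and they
    are excluded from thresholded voxel sets.
    """

    values: np.ndarray
    kind: str  # one of {"r", "t", "salience", "bsr", "count"}
    n: int
    df: int | None = None
    provenance: str = ""
    flags: np.ndarray | None = None
    mask: VoxelMask | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("StatMap values must be a 1D masked-voxel vector")
        if self.kind == "r" and np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise ValueError("r-kind values must lie in [-1, 1]")
        if self.kind == "t" and (self.df is None or self.df < 1):
            raise ValueError("t-kind maps need df >= 1")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.values.shape:
                raise ValueError("flags must match values in length")
        if self.mask is not None and self.mask.n_voxels != self.values.size:
            raise ValueError("values length must equal mask.n_voxels")

    @property
    def n_voxels(self) -> int:
        return self.values.size


def _design(covariates: np.ndarray, n: int) -> np.ndarray:
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows must match the participant count")
    return np.column_stack([np.ones(n), C])


def residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of ``values`` (vector or n x k matrix) against
    [intercept, covariates].

    Residuals are exactly orthogonal to the intercept and every covariate
    column. Raises on a rank-deficient design (e.g. a zero-variance
    covariate, which is collinear with the intercept) or too few rows.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    D = _design(covariates, n)
    q = D.shape[1] - 1
    if n < q + 2:
        raise ValueError(f"need at least {q + 2} rows to residualize against {q} covariates")
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient design: covariates collinear (after intercept)")
    beta, *_ = np.linalg.lstsq(D, values, rcond=None)
    return values - D @ beta


def _corr_columns(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of each column of X with y.

    Returns (r, zero_variance_flags); zero-variance columns get r = 0.
    Shared by the univariate and PLS arms so both use one convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if y.shape != (n,):
        raise ValueError("y must be one value per participant")
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0.0:
        raise ValueError("behavior vector is constant; correlation undefined")
    Xc = X - X.mean(axis=0)
    xnorm = np.linalg.norm(Xc, axis=0)
    flags = xnorm == 0.0
    denom = np.where(flags, 1.0, xnorm) * ynorm
    r = (Xc.T @ yc) / denom
    r[flags] = 0.0
    return np.clip(r, -1.0, 1.0), flags


def voxelwise_corr(X: np.ndarray, y: np.ndarray, provenance: str = "") -> StatMap:
    """Pearson correlation of every voxel column of X with behavior y."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 participants")
    r, flags = _corr_columns(X, y)
    return StatMap(values=r, kind="r", n=X.shape[0], flags=flags, provenance=provenance)


def r_to_t(rmap: StatMap, n: int | None = None, q_covariates: int = 0) -> StatMap:
    """Convert a correlation map to t with df = n - 2 - q_covariates.

    t = r * sqrt(df / (1 - r^2)); |r| = 1 maps to +-T_CAP.
    """
    if rmap.kind != "r":
        raise ValueError("r_to_t expects an r-kind map")
    n = rmap.n if n is None else n
    df = n - 2 - q_covariates
    if df < 1:
        raise ValueError(f"df = n - 2 - q = {df} < 1")
    r = rmap.values
    one_minus = 1.0 - r**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / one_minus)
    t = np.where(one_minus <= 0.0, np.sign(r) * T_CAP, t)
    t = np.clip(t, -T_CAP, T_CAP)
    return StatMap(
        values=t,
        kind="t",
        n=n,
        df=df,
        flags=rmap.flags,
        mask=rmap.mask,
        provenance=rmap.provenance,
    )


def group_ttest(X: np.ndarray, provenance: str = "") -> StatMap:
    """One-sample t per voxel against 0, df = n - 1 (task-effect surrogate).

    Zero-variance voxels: t = +-T_CAP when the common value is nonzero
    (an exact, noiseless effect), 0 when it is zero; both are flagged.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    flags = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(flags, np.sign(mean) * T_CAP, t)
    t = np.clip(t, -T_CAP, T_CAP)
    return StatMap(values=t, kind="t", n=n, df=n - 1, flags=flags, provenance=provenance)


def threshold_map(smap: StatMap, threshold: float, tail: str = "positive") -> np.ndarray:
    """Boolean suprathreshold voxel set (inclusive comparison).

    positive: value >= threshold; negative: value <= -threshold;
    absolute: the union. Flagged (degenerate) voxels never enter the set.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    v = smap.values
    if tail == "positive":
        out = v >= threshold
    elif tail == "negative":
        out = v <= -threshold
    elif tail == "absolute":
        out = (v >= threshold) | (v <= -threshold)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    if smap.flags is not None:
        out = out & ~smap.flags
    return out
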