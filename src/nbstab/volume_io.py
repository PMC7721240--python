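"""NIfTI volume/mask I/O and masked-vector conversion.

All statistical maps in this package live on a fixed *masked voxel vector*:
the in-mask voxels of a 3D grid, enumerated in ascending linear index with
the **first axis fastest** (Fortran ravel order). The order is a property of
the mask alone, so every map computed against the same mask shares it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "VoxelMask",
    "CohortTable",
    "GridMismatchError",
    "load_volume",
    "save_volume",
    "vectorize",
    "devectorize",
    "read_cohort_table",
]


class GridMismatchError(ValueError):
    """Two volumes/masks do not live on the same sampling grid."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D sampling grid: array shape plus voxel-to-mm affine.

    Parameters
    ----------
    shape
        Number of voxels along each of the three axes.
    affine
        4x4 matrix mapping voxel indices to mm coordinates (NIfTI convention).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three entries >= 1, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_size_mm: float = 3.0) -> "VolumeGrid":
        """Axis-aligned grid with isotropic voxels (default 3 mm)."""
        affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
        return cls(shape=tuple(shape), affine=affine)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "VolumeGrid", tol_mm: float = 1e-4) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol_mm)
        )

    def require_match(self, other: "VolumeGrid", tol_mm: float = 1e-4) -> None:
        if not self.matches(other, tol_mm):
            raise GridMismatchError(
                f"grid mismatch: shape {self.shape} affine\n{self.affine}\n"
                f"vs shape {other.shape} affine\n{other.affine}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.array_equal(self.affine, other.affine)

    def __hash__(self) -> int:
        return hash((self.shape, self.affine.tobytes()))


@dataclass(frozen=True)
class VoxelMask:
    """Boolean analysis mask over a :class:`VolumeGrid`.

    Exposes the fixed linear voxel order used throughout the pipeline
    (ascending linear index, first axis fastest).
    """

    grid: VolumeGrid
    in_mask: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.in_mask, dtype=bool)
        if arr.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {arr.shape} does not match grid shape {self.grid.shape}"
            )
        if int(arr.sum()) < 1:
            raise ValueError("mask must contain at least one voxel")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "in_mask", arr)
        flat = np.flatnonzero(arr.ravel(order="F"))
        flat.setflags(write=False)
        object.__setattr__(self, "_flat_index", flat)

    @property
    def n_voxels(self) -> int:
        return int(self._flat_index.size)

    @property
    def flat_index(self) -> np.ndarray:
        """Linear (Fortran-order) indices of in-mask voxels, ascending."""
        return self._flat_index

    def ijk(self) -> np.ndarray:
        """(n_voxels, 3) voxel coordinates in the fixed vector order."""
        return np.column_stack(np.unravel_index(self._flat_index, self.grid.shape, order="F"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelMask):
            return NotImplemented
        return self.grid == other.grid and np.array_equal(self.in_mask, other.in_mask)

    def __hash__(self) -> int:
        return hash((self.grid, self.in_mask.tobytes()))


def vectorize(volume: np.ndarray, mask: VoxelMask) -> np.ndarray:
    """Extract in-mask voxel values as a 1D vector in the fixed order."""
    volume = np.asarray(volume)
    if volume.shape != mask.grid.shape:
        raise GridMismatchError(
            f"volume shape {volume.shape} does not match mask grid {mask.grid.shape}"
        )
    return volume.ravel(order="F")[mask.flat_index].copy()


def devectorize(values: np.ndarray, mask: VoxelMask, fill: float = np.nan) -> np.ndarray:
    """Scatter a masked vector back onto the 3D grid.

    Out-of-mask voxels receive ``fill`` (NaN by default, so thresholding a
    written map can never pick up voxels outside the analysis mask).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size != mask.n_voxels:
        raise ValueError(f"expected vector of length {mask.n_voxels}, got shape {values.shape}")
    flat = np.full(mask.grid.n_voxels, fill, dtype=float)
    flat[mask.flat_index] = values
    return flat.reshape(mask.grid.shape, order="F")


def load_volume(
    path: str | Path, expected_grid: VolumeGrid | None = None
) -> tuple[np.ndarray, VolumeGrid]:
    """Load a 3D NIfTI volume, returning data and its grid.

    Raises on missing file, non-3D data, or (if ``expected_grid`` is given)
    any grid mismatch beyond 1e-4 mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    grid = VolumeGrid(shape=data.shape, affine=np.asarray(img.affine))
    if expected_grid is not None:
        expected_grid.require_match(grid)
    return data, grid


def save_volume(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> Path:
    """Write a 3D volume as single-file NIfTI (32-bit float data)."""
    data = np.asarray(data)
    if data.shape != grid.shape:
        raise GridMismatchError(f"data shape {data.shape} does not match grid {grid.shape}")
    img = nib.Nifti1Image(data.astype(np.float32), grid.affine)
    path = Path(path)
    nib.save(img, str(path))
    return path


@dataclass
class CohortTable:
    """Typed participant table: id, behavior, nuisance covariates, strata.

    Row order is preserved from the source file; participant ids are unique.
    """

    ids: list[str]
    behavior: np.ndarray
    covariates: pd.DataFrame
    strata: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("participant ids must be unique")
        self.behavior = np.asarray(self.behavior, dtype=float)
        if np.isnan(self.behavior).any():
            raise ValueError("behavior contains missing values")
        n = len(self.ids)
        if self.behavior.shape != (n,) or len(self.covariates) != n:
            raise ValueError("id, behavior and covariate row counts disagree")
        if self.strata is not None:
            self.strata = np.asarray(self.strata)
            if self.strata.shape != (n,):
                raise ValueError("stratum labels must match the participant count")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"participant_id": self.ids, "behavior": self.behavior})
        for col in self.covariates.columns:
            df[col] = np.asarray(self.covariates[col])
        if self.strata is not None:
            df["stratum"] = self.strata
        return df


def read_cohort_table(
    path: str | Path,
    id_col: str = "participant_id",
    behavior_col: str = "behavior",
    covariate_cols: tuple[str, ...] = ("age", "fd"),
    stratum_col: str | None = "stratum",
) -> CohortTable:
    """Read a delimited cohort table (CSV or TSV, by extension).

    Column names are configurable; a stratum column is optional and used by
    the stratified subsampler when present.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    required = [id_col, behavior_col, *covariate_cols]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    behavior = pd.to_numeric(df[behavior_col], errors="coerce").to_numpy()
    if np.isnan(behavior).any():
        raise ValueError(f"{path}: behavior column {behavior_col!r} has non-numeric/missing values")
    strata = None
    if stratum_col is not None and stratum_col in df.columns:
        strata = df[stratum_col].to_numpy()
    covs = df[list(covariate_cols)].apply(pd.to_numeric)
    return CohortTable(
        ids=list(df[id_col].astype(str)),
        behavior=behavior,
        covariates=covs.reset_index(drop=True),
        strata=strata,
    )
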