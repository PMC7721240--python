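"""Cross-subsample stability metrics for statistical maps.

Three views of agreement between maps computed on disjoint subsamples:

* Spearman rho over the *unthresholded* values of every masked voxel,
* the Jaccard index (intersection over union) of suprathreshold voxel
  sets (threshold 3, positive tail by default), and
* penetration maps - per-voxel counts of how many thresholded maps include
  the voxel, reported from a minimum of 2 overlapping maps upward, with no
  clustering applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import StatMap, threshold_map

__all__ = [
    "PenetrationMap",
    "spearman_rho",
    "jaccard",
    "dice",
    "pairwise_similarity",
    "penetration",
    "overlap_summary",
]


@dataclass
class PenetrationMap:
    """Per-voxel overlap counts across the thresholded maps of one size."""

    counts: np.ndarray
    n_maps: int
    min_reported: int = 2

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_maps:
            raise ValueError("counts must lie in [0, n_maps]")

    @property
    def reported(self) -> np.ndarray:
        """Counts with sub-minimum voxels zeroed (the reported volume)."""
        out = self.counts.copy()
        out[out < self.min_reported] = 0
        return out


def _values(m: StatMap | np.ndarray) -> np.ndarray:
    return m.values if isinstance(m, StatMap) else np.asarray(m, dtype=float)


def spearman_rho(map_a: StatMap | np.ndarray, map_b: StatMap | np.ndarray) -> float:
    """Spearman rank correlation over all masked voxels (average ranks for
    ties). Raises for constant maps (rho undefined) or length mismatch."""
    a, b = _values(map_a), _values(map_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("maps must be 1D vectors of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 voxels")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("Spearman rho undefined for a constant map")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def jaccard(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """|A n B| / |A u B| for boolean voxel sets over one mask.

    An empty union (nothing suprathreshold in either map) returns 0.0 -
    "nothing replicated" counts as zero stability; callers that need to
    distinguish the degenerate case should check emptiness themselves (the
    pairwise table records a ``both_empty`` flag).
    """
    a = np.asarray(set_a, dtype=bool)
    b = np.asarray(set_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("voxel sets must share a mask")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(a & b) / union)


def dice(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Dice coefficient 2|AnB| / (|A| + |B|); convenience derived metric."""
    a = np.asarray(set_a, dtype=bool)
    b = np.asarray(set_b, dtype=bool)
    denom = np.count_nonzero(a) + np.count_nonzero(b)
    if denom == 0:
        return 0.0
    return float(2 * np.count_nonzero(a & b) / denom)


def _check_common_length(maps: list[StatMap]) -> int:
    lengths = {m.n_voxels for m in maps}
    if len(lengths) != 1:
        raise ValueError(f"maps must share one mask; got lengths {sorted(lengths)}")
    if len({m.mask for m in maps if m.mask is not None}) > 1:
        raise ValueError("maps carry different masks")
    return lengths.pop()


def pairwise_similarity(
    maps: list[StatMap],
    threshold: float = 3.0,
    tail: str = "positive",
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """All unordered map pairs: Spearman rho on unthresholded values,
    Jaccard and overlap count on thresholded sets.

    Returns a tidy frame with one row per pair and columns
    (map_a, map_b, rho, jaccard, n_overlap, both_empty).
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    _check_common_length(maps)
    if ids is None:
        ids = [str(i) for i in range(len(maps))]
    sets = [threshold_map(m, threshold, tail) for m in maps]
    rows = []
    for i, j in combinations(range(len(maps)), 2):
        a, b = sets[i], sets[j]
        union = int(np.count_nonzero(a | b))
        rows.append(
            {
                "map_a": ids[i],
                "map_b": ids[j],
                "rho": spearman_rho(maps[i], maps[j]),
                "jaccard": jaccard(a, b),
                "n_overlap": int(np.count_nonzero(a & b)),
                "both_empty": union == 0,
            }
        )
    return pd.DataFrame(rows)


def penetration(
    maps: list[StatMap],
    threshold: float = 3.0,
    tail: str = "positive",
    min_reported: int = 2,
) -> PenetrationMap:
    """Per-voxel count of thresholded maps containing each voxel.

    No clustering is applied to the thresholded images. The reported volume
    zeroes voxels below ``min_reported`` (default 2) overlapping maps.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    _check_common_length(maps)
    counts = np.sum([threshold_map(m, threshold, tail) for m in maps], axis=0)
    return PenetrationMap(counts=counts, n_maps=len(maps), min_reported=min_reported)


def overlap_summary(pairs: pd.DataFrame, by: tuple[str, ...] = ("size", "method")) -> pd.DataFrame:
    """Per-group means/SDs of pairwise rho, Jaccard and overlap counts.

    ``pairs`` is a concatenation of :func:`pairwise_similarity` tables with
    grouping columns (by default size and method) attached.
    """
    group_cols = [c for c in by if c in pairs.columns]
    if not group_cols:
        raise ValueError(f"no grouping columns {by} present in the table")
    agg = (
        pairs.groupby(group_cols, sort=True)
        .agg(
            mean_rho=("rho", "mean"),
            sd_rho=("rho", "std"),
            mean_jaccard=("jaccard", "mean"),
            sd_jaccard=("jaccard", "std"),
            mean_overlap=("n_overlap", "mean"),
            n_pairs=("rho", "size"),
        )
        .reset_index()
    )
    return agg
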