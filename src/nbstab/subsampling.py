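"""Disjoint, optionally age-stratified subsample draws.

All subsamples of a given size contain different participants (sampling
without replacement across the subsamples of that size); draws at different
sizes are fresh and independent, so the same participant may recur across
sizes. Stratified draws place exactly ``size / n_strata`` members of each
stratum in every subsample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SubsampleSchedule",
    "SubsampleSet",
    "default_schedule",
    "draw_subsamples",
    "DALLAS_SCHEDULE",
    "HCP_SCHEDULE",
]

#: Lifespan design: 12x10, 24x7, 36x4, 48x3, 60x2, 72x2, 84x2 (171 participants).
DALLAS_SCHEDULE: tuple[tuple[int, int], ...] = (
    (12, 10),
    (24, 7),
    (36, 4),
    (48, 3),
    (60, 2),
    (72, 2),
    (84, 2),
)

#: Young-adult design: 20-80 x10, 100x8, 120x7, 140x6, 160x5, 210x4, 280x3, 420x2.
HCP_SCHEDULE: tuple[tuple[int, int], ...] = (
    (20, 10),
    (40, 10),
    (60, 10),
    (80, 10),
    (100, 8),
    (120, 7),
    (140, 6),
    (160, 5),
    (210, 4),
    (280, 3),
    (420, 2),
)


@dataclass(frozen=True)
class SubsampleSchedule:
    """Ordered list of (subsample size, number of subsamples) entries."""

    entries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        entries = tuple((int(s), int(c)) for s, c in self.entries)
        if any(s <= 0 or c <= 0 for s, c in entries):
            raise ValueError("sizes and counts must be strictly positive")
        object.__setattr__(self, "entries", entries)

    def validate_for(self, n_total: int) -> None:
        for size, count in self.entries:
            if size * count > n_total:
                raise ValueError(
                    f"schedule entry ({size}, {count}) needs {size * count} "
                    f"participants but the cohort has {n_total}"
                )

    @property
    def sizes(self) -> list[int]:
        return [s for s, _ in self.entries]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def default_schedule(design: str) -> SubsampleSchedule:
    """The two built-in schedules, by design name ('dallas' or 'hcp')."""
    if design == "dallas":
        return SubsampleSchedule(DALLAS_SCHEDULE)
    if design == "hcp":
        return SubsampleSchedule(HCP_SCHEDULE)
    raise ValueError(f"unknown design {design!r} (expected 'dallas' or 'hcp')")


@dataclass(frozen=True)
class SubsampleSet:
    """Pairwise-disjoint participant index sets, all of one size."""

    size: int
    index_sets: tuple[np.ndarray, ...]
    seed: int
    stratified: bool = False

    def __post_init__(self) -> None:
        sets = tuple(np.asarray(s, dtype=int) for s in self.index_sets)
        seen: set[int] = set()
        for s in sets:
            if s.size != self.size:
                raise ValueError("every index set must have length == size")
            as_set = set(int(i) for i in s)
            if len(as_set) != s.size:
                raise ValueError("index set contains repeated participants")
            if seen & as_set:
                raise ValueError("index sets are not pairwise disjoint")
            seen |= as_set
        for s in sets:
            s.setflags(write=False)
        object.__setattr__(self, "index_sets", sets)

    @property
    def n_subsamples(self) -> int:
        return len(self.index_sets)

    def to_json(self, path: str | Path, ids: list[str] | None = None) -> Path:
        """Serialize for exact re-runs (indices, and ids when given)."""
        payload = {
            "size": self.size,
            "seed": self.seed,
            "stratified": self.stratified,
            "index_sets": [[int(i) for i in s] for s in self.index_sets],
        }
        if ids is not None:
            payload["id_sets"] = [[ids[i] for i in s] for s in self.index_sets]
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SubsampleSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            size=payload["size"],
            index_sets=tuple(np.asarray(s, dtype=int) for s in payload["index_sets"]),
            seed=payload["seed"],
            stratified=payload.get("stratified", False),
        )


def _rng_for(seed: int, size: int) -> np.random.Generator:
    # Per-size substream of the master seed: adding or reordering sizes in a
    # schedule never changes the draw at any other size.
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(size)]))


def draw_subsamples(
    n_total: int,
    size: int,
    count: int,
    strata: np.ndarray | None = None,
    seed: int = 0,
) -> SubsampleSet:
    """Draw ``count`` pairwise-disjoint subsamples of ``size`` participants.

    With ``strata`` (per-participant labels, length ``n_total``), each
    subsample contains exactly ``size / n_strata`` members of every stratum;
    ``size`` must be divisible by the number of strata and each stratum must
    hold at least ``count * size / n_strata`` members, otherwise a clear
    error is raised rather than a silently imbalanced draw.
    """
    if size <= 0 or count <= 0:
        raise ValueError("size and count must be positive")
    if size * count > n_total:
        raise ValueError(
            f"cannot draw {count} disjoint subsamples of {size} from {n_total} participants"
        )
    rng = _rng_for(seed, size)
    if strata is None:
        perm = rng.permutation(n_total)
        sets = tuple(np.sort(perm[j * size : (j + 1) * size]) for j in range(count))
        return SubsampleSet(size=size, index_sets=sets, seed=seed)

    strata = np.asarray(strata)
    if strata.shape != (n_total,):
        raise ValueError("strata must be one label per participant")
    levels = np.unique(strata)
    k = len(levels)
    if size % k != 0:
        raise ValueError(f"stratified draw needs size divisible by {k} strata, got {size}")
    per = size // k
    members = {lev: np.flatnonzero(strata == lev) for lev in levels}
    for lev, idx in members.items():
        if idx.size < per * count:
            raise ValueError(
                f"stratum {lev!r} has {idx.size} members but the draw needs {per * count}"
            )
    chunks: list[list[np.ndarray]] = []
    for lev in levels:
        perm = rng.permutation(members[lev])
        chunks.append([perm[j * per : (j + 1) * per] for j in range(count)])
    sets = tuple(
        np.sort(np.concatenate([chunks[s][j] for s in range(k)])) for j in range(count)
    )
    return SubsampleSet(size=size, index_sets=sets, seed=seed, stratified=True)
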