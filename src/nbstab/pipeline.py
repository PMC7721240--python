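"""End-to-end stability experiment.

cohort -> subsample schedule -> per-subsample univariate (r -> t) and
behavioral-PLS maps -> pairwise similarity, penetration and summary tables.

Age and mean FD are residualized from behavior and from every voxel before
both analysis arms. By default the residualization is computed *within each
subsample* (each subsample is its own analysis sample); computing it once on
the full cohort is available as ``residualize_scope="cohort"``.

Every random element (subsample draws, permutations, bootstraps) is derived
deterministically from the master seed, so a full run is a pure function of
(config, seed) and re-runs are byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .pls import PLSResult, run_behavioral_pls
from .similarity import PenetrationMap, overlap_summary, pairwise_similarity, penetration
from .subsampling import SubsampleSchedule, SubsampleSet, default_schedule, draw_subsamples
from .synthetic import Cohort, make_preset_cohort, read_cohort
from .univariate import StatMap, r_to_t, residualize, voxelwise_corr
from .volume_io import devectorize, save_volume

logger = logging.getLogger("nbstab")

__all__ = [
    "ExperimentConfig",
    "StabilityReport",
    "run_experiment",
    "report_tables",
    "compare_methods",
]

METHODS = ("univariate", "pls")


@dataclass
class ExperimentConfig:
    """Settings of one stability experiment (YAML-serializable).

    ``cohort`` is either ``{"preset": "dallas_like"|"hcp_like", ...}`` with
    optional generator overrides (pattern_kind, n, grid_shape, rho_strong,
    support_radius_vox, ...) or ``{"path": <directory>}`` for data on disk.
    ``schedule`` is a design name ('dallas'/'hcp') or an explicit list of
    [size, n_subsamples] pairs. Resampling defaults are the standard
    1,000 permutations / 1,000 bootstraps; reduced values are accepted for
    desk-scale runs.
    """

    cohort: dict = field(default_factory=lambda: {"preset": "dallas_like"})
    schedule: str | list = "dallas"
    threshold: float = 3.0
    tail: str = "positive"
    n_perm: int = 1000
    n_boot: int = 1000
    seed: int = 0
    out_dir: str | None = None
    residualize_scope: str = "subsample"
    use_strata: bool = True
    min_penetration: int = 2
    save_penetration: bool = True
    save_maps: bool = False
    plots: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.residualize_scope not in ("subsample", "cohort"):
            raise ValueError("residualize_scope must be 'subsample' or 'cohort'")

    def resolve_schedule(self) -> SubsampleSchedule:
        if isinstance(self.schedule, str):
            return default_schedule(self.schedule)
        return SubsampleSchedule(tuple((int(s), int(c)) for s, c in self.schedule))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> Path:
        payload = asdict(self)
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
        return path


@dataclass
class StabilityReport:
    """All tables and maps of one experiment run."""

    config: ExperimentConfig
    similarity_pairs: pd.DataFrame
    pls_table: pd.DataFrame
    summary: pd.DataFrame
    penetration_maps: dict[tuple[int, str], PenetrationMap]
    subsample_sets: dict[int, SubsampleSet]
    cohort_n: int
    n_voxels: int
    maps: dict[tuple[int, int, str], StatMap] | None = None

    def validate_complete(self) -> None:
        """Every (size, subsample) in the schedule has exactly one
        univariate and one PLS record; raise otherwise."""
        schedule = self.config.resolve_schedule()
        expected = {(s, j) for s, c in schedule for j in range(c)}
        got = {(int(r.size), int(r.subsample)) for r in self.pls_table.itertuples()}
        if got != expected:
            raise ValueError(f"incomplete PLS records: missing {sorted(expected - got)}")
        per_size = self.similarity_pairs.groupby(["size", "method"]).size()
        for size, count in schedule:
            want = count * (count - 1) // 2
            for method in METHODS:
                if int(per_size.get((size, method), 0)) != want:
                    raise ValueError(f"incomplete similarity rows at size {size} ({method})")


def _build_cohort(config: ExperimentConfig) -> Cohort:
    source = dict(config.cohort)
    if "path" in source:
        return read_cohort(source["path"])
    preset = source.pop("preset", "dallas_like")
    grid_shape = source.pop("grid_shape", None)
    if grid_shape is not None:
        from .volume_io import VolumeGrid

        source["grid"] = VolumeGrid.isotropic(tuple(grid_shape))
    return make_preset_cohort(preset, seed=config.seed, **source)


def _pls_seed(master: int, size: int, subsample: int) -> int:
    # stable per-(size, subsample) stream, independent of schedule order
    return int(
        np.random.SeedSequence([int(master), int(size), int(subsample), 7]).generate_state(1)[0]
        % (2**31)
    )


def run_experiment(config: ExperimentConfig, cohort: Cohort | None = None) -> StabilityReport:
    """Execute the full experiment described by ``config``.

    ``cohort`` may be supplied directly (e.g. an already-simulated cohort);
    otherwise it is built from ``config.cohort``. Artifacts are written to
    ``config.out_dir`` when set.
    """
    if cohort is None:
        cohort = _build_cohort(config)
    schedule = config.resolve_schedule()
    schedule.validate_for(cohort.n)

    X_full, y_full, C_full = cohort.X, cohort.y, cohort.C
    if config.residualize_scope == "cohort":
        X_full = residualize(X_full, C_full)
        y_full = residualize(y_full, C_full)

    strata = cohort.strata if config.use_strata else None
    q = C_full.shape[1]

    pair_tables: list[pd.DataFrame] = []
    pls_rows: list[dict] = []
    pen: dict[tuple[int, str], PenetrationMap] = {}
    subsample_sets: dict[int, SubsampleSet] = {}
    kept_maps: dict[tuple[int, int, str], StatMap] = {}

    for size, count in schedule:
        sset = draw_subsamples(cohort.n, size, count, strata=strata, seed=config.seed)
        subsample_sets[size] = sset
        t_maps: list[StatMap] = []
        bsr_maps: list[StatMap] = []
        for j, idx in enumerate(sset.index_sets):
            t0 = time.perf_counter()
            Xs, ys, Cs = X_full[idx], y_full[idx], C_full[idx]
            if config.residualize_scope == "subsample":
                Xs = residualize(Xs, Cs)
                ys = residualize(ys, Cs)
            prov = f"size={size} subsample={j}"
            rmap = voxelwise_corr(Xs, ys, provenance=f"univariate r {prov}")
            rmap.mask = cohort.mask
            tmap = r_to_t(rmap, n=size, q_covariates=q)
            t_maps.append(tmap)
            seed_j = _pls_seed(config.seed, size, j)
            pls = run_behavioral_pls(Xs, ys, config.n_perm, config.n_boot, seed=seed_j)
            bsr_maps.append(
                StatMap(
                    values=pls.bsr, kind="bsr", n=size, flags=pls.bsr_flags,
                    mask=cohort.mask, provenance=f"pls bsr {prov}",
                )
            )
            pls_rows.append(
                {
                    "size": size,
                    "subsample": j,
                    "n": size,
                    "singular_value": pls.singular_value,
                    "r_brainscore_behavior": pls.r_brainscore_behavior,
                    "perm_p": pls.perm_p,
                    "seed": seed_j,
                }
            )
            logger.info(
                "size=%d subsample=%d seed=%d elapsed=%.2fs", size, j, seed_j,
                time.perf_counter() - t0,
            )
            if config.save_maps:
                kept_maps[(size, j, "univariate")] = tmap
                kept_maps[(size, j, "pls")] = bsr_maps[-1]
        ids = [f"n{size}_s{j}" for j in range(count)]
        for method, maps in (("univariate", t_maps), ("pls", bsr_maps)):
            table = pairwise_similarity(maps, config.threshold, config.tail, ids=ids)
            table.insert(0, "size", size)
            table.insert(1, "method", method)
            pair_tables.append(table)
            pen[(size, method)] = penetration(
                maps, config.threshold, config.tail, config.min_penetration
            )

    similarity_pairs = pd.concat(pair_tables, ignore_index=True)
    pls_table = pd.DataFrame(pls_rows)
    summary = overlap_summary(similarity_pairs)
    report = StabilityReport(
        config=config,
        similarity_pairs=similarity_pairs,
        pls_table=pls_table,
        summary=summary,
        penetration_maps=pen,
        subsample_sets=subsample_sets,
        cohort_n=cohort.n,
        n_voxels=cohort.mask.n_voxels,
        maps=kept_maps if config.save_maps else None,
    )
    report.validate_complete()
    if config.out_dir is not None:
        report_tables(report, config.out_dir, plots=config.plots, cohort=cohort)
    return report


_FLOAT_FMT = "%.10g"


def report_tables(
    report: StabilityReport,
    out_dir: str | Path,
    plots: bool = False,
    cohort: Cohort | None = None,
) -> dict[str, Path]:
    """Write tidy CSVs (and optional plots / penetration volumes).

    Files: ``similarity_by_size.csv`` (per size x method mean/sd rho and
    Jaccard), ``pls_by_subsample.csv`` (one row per PLS fit),
    ``overlap_by_size.csv`` (mean overlapping-voxel counts), plus the raw
    ``similarity_pairs.csv`` and per-size subsample JSONs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sim = report.summary[
        ["size", "method", "mean_rho", "sd_rho", "mean_jaccard", "sd_jaccard", "n_pairs"]
    ]
    paths["similarity_by_size"] = out / "similarity_by_size.csv"
    sim.to_csv(paths["similarity_by_size"], index=False, float_format=_FLOAT_FMT)

    paths["pls_by_subsample"] = out / "pls_by_subsample.csv"
    report.pls_table.to_csv(paths["pls_by_subsample"], index=False, float_format=_FLOAT_FMT)

    ov = report.summary[["size", "method", "mean_overlap", "n_pairs"]]
    paths["overlap_by_size"] = out / "overlap_by_size.csv"
    ov.to_csv(paths["overlap_by_size"], index=False, float_format=_FLOAT_FMT)

    paths["similarity_pairs"] = out / "similarity_pairs.csv"
    report.similarity_pairs.to_csv(paths["similarity_pairs"], index=False, float_format=_FLOAT_FMT)

    subs_dir = out / "subsamples"
    subs_dir.mkdir(exist_ok=True)
    for size, sset in report.subsample_sets.items():
        sset.to_json(subs_dir / f"subsamples_n{size}.json")

    report.config.to_yaml(out / "config_used.yaml")

    if report.config.save_penetration and cohort is not None:
        for (size, method), pmap in report.penetration_maps.items():
            vol = devectorize(pmap.reported.astype(float), cohort.mask, fill=0.0)
            save_volume(vol, cohort.mask.grid, out / f"penetration_n{size}_{method}.nii.gz")

    if plots:
        paths.update(_plot_curves(report, out))
    return paths


def _plot_curves(report: StabilityReport, out: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, Path] = {}
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for method in METHODS:
        sub = report.summary[report.summary["method"] == method]
        axes[0].plot(sub["size"], sub["mean_rho"], "o-", label=method)
        axes[1].plot(sub["size"], sub["mean_jaccard"], "o-", label=method)
    axes[0].set(xlabel="sample size", ylabel="mean pairwise Spearman rho")
    axes[1].set(xlabel="sample size", ylabel="mean pairwise Jaccard")
    axes[0].legend()
    fig.tight_layout()
    paths["similarity_plot"] = out / "similarity_vs_size.png"
    fig.savefig(paths["similarity_plot"], dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    g = report.pls_table.groupby("size")
    axes[0].plot(report.pls_table["size"], report.pls_table["r_brainscore_behavior"], "k.", alpha=0.5)
    axes[0].plot(g["r_brainscore_behavior"].mean().index, g["r_brainscore_behavior"].mean(), "r--")
    axes[0].set(xlabel="sample size", ylabel="brain score-behavior r")
    axes[1].semilogy(report.pls_table["size"], report.pls_table["perm_p"], "k.", alpha=0.5)
    axes[1].axhline(0.05, color="b")
    axes[1].set(xlabel="sample size", ylabel="LV permutation p")
    fig.tight_layout()
    paths["pls_plot"] = out / "pls_vs_size.png"
    fig.savefig(paths["pls_plot"], dpi=120)
    plt.close(fig)
    return paths


def compare_methods(report: StabilityReport) -> dict:
    """Paired comparison of Jaccard between the two arms across sizes.

    Computes per-size mean Jaccard for each method, the paired differences
    (PLS - univariate), and a paired t test over sizes (df = n_sizes - 1).
    """
    wide = report.summary.pivot(index="size", columns="method", values="mean_jaccard")
    if wide.shape[0] < 2 or set(METHODS) - set(wide.columns):
        raise ValueError("need both methods at >= 2 sizes for a paired comparison")
    diff = wide["pls"] - wide["univariate"]
    if np.allclose(diff, 0.0):
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_rel(wide["pls"], wide["univariate"])
    return {
        "per_size": wide.reset_index(),
        "differences": diff.to_numpy(),
        "t": float(t_stat),
        "df": int(wide.shape[0] - 1),
        "p": float(p_val),
    }
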