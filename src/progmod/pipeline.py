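"""Config-driven end-to-end progression analysis.

Orchestrates preprocessing, the per-group differential equation model, the
per-group event-based model (Gaussian mixtures for volumes, KDE mixtures
for cognitive scores) and the ordering statistics, writing all stage
outputs plus a manifest (config hash, seed, content hashes) so a rerun with
the same config and input is reproducible.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import (ControlReference, ID_COLUMNS, adjust_covariates,
                         apply_floor_rule_table, orient_abnormality,
                         zscore_to_controls)
from .dem import (Trajectory, bootstrap_trajectories, compare_trajectory_values,
                  fit_dem, stage_subjects_dem)
from .kde_ebm import (EventSequence, fit_mixtures, find_ml_sequence, mcmc_sample,
                      positional_variance, positions_from_sequences,
                      stage_subjects_ebm, thin_chain, bootstrap_sequences)
from .ordering_stats import (between_group_position_test, bonferroni_control,
                             within_group_order_test)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "render_reports"]

log = logging.getLogger("progmod.pipeline")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialisable to YAML/JSON."""

    biomarkers: Sequence[str]
    directions: Mapping[str, str]
    groups: Sequence[str]
    input_path: str | None = None
    flavours: Mapping[str, str] = field(default_factory=dict)  # gaussian | kde
    covariates: Sequence[str] = ("tiv", "age", "gender", "scanner", "site")
    floors: Mapping[str, float] = field(default_factory=dict)
    dem_n_boot: int = 20
    dem_comparison_times: Sequence[float] = (-10.0, 0.0, 10.0)
    dem_grid_size: int = 200
    ebm_mcmc_iterations: int = 10_000
    ebm_thinning: int = 100
    ebm_n_boot: int = 0                # >0 adds bootstrap positional variance
    ebm_n_starts: int = 4
    position_source: str = "mcmc"      # mcmc | bootstrap, for ordering stats
    alpha: float = 0.05
    output_dir: str = "progmod_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.biomarkers:
            raise ValueError("biomarker list is empty")
        missing = [b for b in self.biomarkers if b not in self.directions]
        if missing:
            raise ValueError(f"no abnormality direction for: {missing}")
        if self.position_source not in ("mcmc", "bootstrap"):
            raise ValueError("position_source must be 'mcmc' or 'bootstrap'")
        if self.position_source == "bootstrap" and self.ebm_n_boot < 1:
            raise ValueError("bootstrap position source requires ebm_n_boot >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory pipeline outputs (also written under ``output_dir``)."""

    config: RunConfig
    preprocessed: pd.DataFrame
    trajectories: dict[str, dict[str, Trajectory]]          # group -> biomarker
    dem_ensembles: dict[str, dict[str, list[Trajectory]]]
    dem_comparisons: pd.DataFrame
    dem_stages: dict[str, pd.DataFrame]
    ml_sequences: dict[str, EventSequence]
    positional_variances: dict[str, pd.DataFrame]
    ebm_stages: dict[str, pd.DataFrame]
    within_tests: pd.DataFrame
    between_tests: pd.DataFrame
    manifest: dict


def _stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream below 2**31."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, table: pd.DataFrame | None = None) -> RunResult:
    """Execute preprocess → per-group DEM → per-group EBM → ordering stats.

    ``table`` may be passed directly; otherwise ``config.input_path`` is
    read as CSV. All stochastic stages draw their seeds from
    ``config.seed`` via stage-specific substreams.
    """
    t_start = time.time()
    if table is None:
        if config.input_path is None:
            raise ValueError("either a table or config.input_path is required")
        table = pd.read_csv(config.input_path)
    missing = [c for c in config.biomarkers if c not in table.columns]
    if missing:
        raise ValueError(f"input table lacks biomarker columns: {missing}")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    biomarkers = list(config.biomarkers)

    # ---- preprocess ------------------------------------------------------
    try:
        work = table
        if config.floors:
            work = apply_floor_rule_table(work, config.floors)
        covs = [c for c in config.covariates if c in work.columns]
        if covs:
            work = adjust_covariates(work, covs, biomarkers=biomarkers)
        reference = ControlReference.from_controls(work, biomarkers,
                                                   directions=config.directions)
        zscored = zscore_to_controls(work, reference, biomarkers)
        oriented = orient_abnormality(work, config.directions, biomarkers)
        oriented_z = orient_abnormality(zscored, config.directions, biomarkers)
    except Exception as err:
        raise RuntimeError(f"stage preprocess failed: {err}") from err
    oriented_z.to_csv(outdir / "preprocessed.csv", index=False)
    log.info("preprocess done (%.1fs)", time.time() - t_start)

    # ---- DEM per group ---------------------------------------------------
    trajectories: dict[str, dict[str, Trajectory]] = {}
    ensembles: dict[str, dict[str, list[Trajectory]]] = {}
    dem_stages: dict[str, pd.DataFrame] = {}
    traj_rows = []
    for group in config.groups:
        sub = oriented[oriented["group"].isin(["control", group])]
        trajectories[group] = {}
        ensembles[group] = {}
        for b in biomarkers:
            t0 = time.time()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    traj = fit_dem(sub, b, grid_size=config.dem_grid_size)
                    ens = bootstrap_trajectories(
                        sub, b, n_boot=config.dem_n_boot,
                        seed=_stage_seed(config.seed, f"dem:{group}:{b}"),
                        grid_size=config.dem_grid_size,
                    ) if config.dem_n_boot > 0 else [traj]
            except ValueError as err:
                raise RuntimeError(f"stage dem failed for {group}/{b}: {err}") from err
            trajectories[group][b] = traj
            ensembles[group][b] = ens
            z_lo = np.percentile([tr.z_at(traj.time) for tr in ens], 2.5, axis=0)
            z_hi = np.percentile([tr.z_at(traj.time) for tr in ens], 97.5, axis=0)
            for t, v, z, lo, hi in zip(traj.time, traj.value, traj.z, z_lo, z_hi):
                traj_rows.append(dict(group=group, biomarker=b, time=t, value=v,
                                      z=z, lo95=lo, hi95=hi))
            log.info("dem %s/%s done (%.1fs)", group, b, time.time() - t0)
        # continuous staging of this group's patients at baseline
        base = oriented_z[(oriented_z["group"] == group)
                          & (oriented_z.get("visit_index", 0) == 0)]
        subject_z = base.set_index("subject_id")[biomarkers]
        stages = stage_subjects_dem(trajectories[group], subject_z)
        dem_stages[group] = pd.DataFrame(
            [dict(subject_id=s.subject_id, stage_time=s.stage_time,
                  residual=s.residual) for s in stages])
        dem_stages[group].to_csv(outdir / f"dem_stages_{group}.csv", index=False)
    pd.DataFrame(traj_rows).to_csv(outdir / "dem_trajectories.csv", index=False)

    dem_comparisons = compare_trajectory_values(
        ensembles, times=config.dem_comparison_times, alpha=config.alpha)
    dem_comparisons.to_csv(outdir / "dem_comparisons.csv", index=False)

    # ---- EBM per group ---------------------------------------------------
    flavour = {b: config.flavours.get(b, "gaussian") for b in biomarkers}
    ml_sequences: dict[str, EventSequence] = {}
    pvds: dict[str, pd.DataFrame] = {}
    ebm_stage_frames: dict[str, pd.DataFrame] = {}
    group_positions: dict[str, dict[str, np.ndarray]] = {}
    for group in config.groups:
        t0 = time.time()
        base = table[(table["group"].isin(["control", group]))]
        if "visit_index" in base.columns:
            base = base[base["visit_index"] == 0]
        # EBM uses covariate-adjusted baseline values (not z-scored)
        base_adj = oriented[oriented.index.isin(base.index)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits = fit_mixtures(base_adj, biomarkers, flavour)
                patients = base_adj[base_adj["group"] == group]
                X = patients.set_index("subject_id")[biomarkers]
                ml = find_ml_sequence(X, fits, n_starts=config.ebm_n_starts,
                                      seed=_stage_seed(config.seed, f"ml:{group}"))
                chain = mcmc_sample(X, fits, ml,
                                    n_iter=config.ebm_mcmc_iterations,
                                    seed=_stage_seed(config.seed, f"mcmc:{group}"))
                thinned = thin_chain(chain, config.ebm_thinning)
                sequences = thinned.sequences()
                if config.ebm_n_boot > 0:
                    boot_seqs = bootstrap_sequences(
                        base_adj, biomarkers, flavour, n_boot=config.ebm_n_boot,
                        seed=_stage_seed(config.seed, f"boot:{group}"),
                        n_starts=config.ebm_n_starts)
                else:
                    boot_seqs = []
                source = boot_seqs if config.position_source == "bootstrap" else sequences
                pvd = positional_variance(source)
                stages = stage_subjects_ebm(X, ml, fits)
        except ValueError as err:
            raise RuntimeError(f"stage ebm failed for {group}: {err}") from err
        ml_sequences[group] = ml
        pvds[group] = pvd.to_frame()
        pvds[group].to_csv(outdir / f"positional_variance_{group}.csv")
        ebm_stage_frames[group] = pd.DataFrame(
            [dict(subject_id=s.subject_id, stage=s.stage) for s in stages])
        ebm_stage_frames[group].to_csv(outdir / f"ebm_stages_{group}.csv", index=False)
        group_positions[group] = {
            b: positions_from_sequences(source, b) for b in biomarkers}
        log.info("ebm %s done (%.1fs): %s", group, time.time() - t0, ml.events)

    with open(outdir / "ebm_sequences.json", "w") as fh:
        json.dump({g: {"events": list(s.events),
                       "log_likelihood": s.log_likelihood}
                   for g, s in ml_sequences.items()}, fh, indent=2)

    # ---- ordering statistics --------------------------------------------
    within_rows = []
    for group in config.groups:
        pos = group_positions[group]
        for bi, bj in itertools.permutations(biomarkers, 2):
            res = within_group_order_test(pos[bi], pos[bj])
            within_rows.append(dict(group=group, biomarker_i=bi, biomarker_j=bj,
                                    statistic=res.statistic, p=res.p_value,
                                    degenerate=res.degenerate))
    within = pd.DataFrame(within_rows)
    if len(within):
        reject, thr = bonferroni_control(within["p"].to_numpy(), alpha=config.alpha)
        within["corrected_threshold"] = thr
        within["significant"] = reject

    between_rows = []
    if len(config.groups) >= 2:
        ga, gb = config.groups[0], config.groups[1]
        for b in biomarkers:
            res = between_group_position_test(group_positions[ga][b],
                                              group_positions[gb][b])
            between_rows.append(dict(biomarker=b, group_1=ga, group_2=gb,
                                     statistic=res.statistic, p=res.p_value,
                                     effect_size=res.effect_size,
                                     degenerate=res.degenerate))
    between = pd.DataFrame(between_rows)
    if len(between):
        reject, thr = bonferroni_control(between["p"].to_numpy(), alpha=config.alpha)
        between["corrected_threshold"] = thr
        between["significant"] = reject
    within.to_csv(outdir / "stats_within.csv", index=False)
    between.to_csv(outdir / "stats_between.csv", index=False)

    # ---- manifest --------------------------------------------------------
    outputs = sorted(p for p in outdir.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "progmod_version": __version__,
        "elapsed_seconds": round(time.time() - t_start, 2),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return RunResult(
        config=config, preprocessed=oriented_z, trajectories=trajectories,
        dem_ensembles=ensembles, dem_comparisons=dem_comparisons,
        dem_stages=dem_stages, ml_sequences=ml_sequences,
        positional_variances=pvds, ebm_stages=ebm_stage_frames,
        within_tests=within, between_tests=between, manifest=manifest,
    )


def render_reports(output_dir, figure_dir=None) -> list[str]:
    """Render figures from a pipeline output directory.

    Produces spaghetti plots (per biomarker/group), trajectory panels with
    subject-stage histograms, and positional variance heatmaps. Missing
    artifacts are skipped with a warning. Returns the figure paths written.
    """
    from . import plotting
    outdir = Path(output_dir)
    figdir = Path(figure_dir) if figure_dir else outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    pre = outdir / "preprocessed.csv"
    if pre.exists():
        table = pd.read_csv(pre)
        written += plotting.spaghetti_plots(table, figdir)
    else:
        warnings.warn("preprocessed.csv missing; skipping spaghetti plots")

    traj = outdir / "dem_trajectories.csv"
    if traj.exists():
        tdf = pd.read_csv(traj)
        for group in tdf["group"].unique():
            stages_path = outdir / f"dem_stages_{group}.csv"
            stages = pd.read_csv(stages_path) if stages_path.exists() else None
            written.append(plotting.trajectory_panel(
                tdf[tdf["group"] == group], group, figdir, stages=stages))
            if pre.exists() and stages is not None:
                written += plotting.hairy_line_plots(
                    pd.read_csv(pre), tdf[tdf["group"] == group], group,
                    stages, figdir)
    else:
        warnings.warn("dem_trajectories.csv missing; skipping trajectory panels")

    for path in sorted(outdir.glob("positional_variance_*.csv")):
        group = path.stem.replace("positional_variance_", "")
        pvd = pd.read_csv(path, index_col=0)
        written.append(plotting.positional_variance_diagram(pvd, group, figdir))
    return written
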