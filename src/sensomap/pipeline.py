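"""End-to-end orchestration: simulate -> preprocess -> beamform ->
connectivity + gating + psychometrics -> group statistics.

Every stage reads and writes on-disk intermediates under one output
directory, so stages are individually re-runnable; every artifact directory
carries a provenance record (config hash, seed, package version).  A rerun
with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .beamformer import (BeamformerWeights, apply_inverse,
                         compute_data_covariance, lcmv_weights,
                         regularize_median_eig)
from .connectivity import ALPHA, BETA, SeedDefinition, seed_fc_map
from .containers import SensorRecording
from .forward import sphere_forward
from .gating import (COMPONENT_WINDOWS_MS, analyze_gating, average_evoked,
                     define_roi_scout, gating_table)
from .mesh import SourceSpace, make_cortical_mesh
from .preprocess import (bandpass_notch, baseline_correct, epoch_evoked,
                         reject_trials, segment_rest)
from .psychometrics import fit_cohort
from .sensors import make_helmet_array
from .simulate import (SimulationConfig, mix_to_sensors, simulate_behavior,
                       simulate_evoked_trials, simulate_source_rest,
                       draw_cohort_truths, subject_rng)
from .stats import TFCEParams, cluster_filter, permutation_fwe, spearman, \
    wilcoxon_signed_rank

logger = logging.getLogger(__name__)

BAND_BY_NAME = {"alpha": ALPHA, "beta": BETA}


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters; defaults follow the emulated study."""

    seed: int = 0
    outdir: str = "sensomap_out"
    # geometry
    mesh_subdivisions: int = 2
    mesh_radius_m: float = 0.07
    n_sensors: int = 48
    sensor_radius_m: float = 0.12
    # simulation
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # preprocessing
    filter_low_hz: float = 0.5
    filter_high_hz: float = 100.0
    notch_hz: float | None = 50.0
    rest_window_ms: float = 2000.0
    epoch_tmin_ms: float = -1500.0
    epoch_tmax_ms: float = 2500.0
    baseline_ms: tuple[float, float] = (-100.0, -5.0)
    ptp_limit_factor: float = 8.0   # reject epochs > factor * median p2p
    # beamformer
    cov_rest_window_ms: tuple[float, float] = (0.0, 2000.0)
    cov_post_window_ms: tuple[float, float] = (0.0, 2500.0)
    projection: str = "weights"
    # connectivity
    fc_bands: tuple[str, ...] = ("alpha", "beta")
    trim_ms: float = 200.0
    fisher: bool = False
    # group statistics
    tfce: TFCEParams = field(default_factory=TFCEParams)
    bonferroni_m: int = 3

    def __post_init__(self) -> None:
        errors = []
        if self.mesh_subdivisions < 1:
            errors.append("mesh_subdivisions must be >= 1")
        if not 0 < self.filter_low_hz < self.filter_high_hz:
            errors.append("need 0 < filter_low_hz < filter_high_hz")
        if self.projection not in ("weights", "leadfield"):
            errors.append("projection must be 'weights' or 'leadfield'")
        for b in self.fc_bands:
            if b not in BAND_BY_NAME:
                errors.append(f"unknown band {b!r}")
        if self.epoch_tmin_ms >= self.epoch_tmax_ms:
            errors.append("epoch_tmin_ms must precede epoch_tmax_ms")
        if self.ptp_limit_factor <= 0:
            errors.append("ptp_limit_factor must be positive")
        if errors:
            raise ValueError("invalid configuration:\n  "
                             + "\n  ".join(errors))

    def resolved_report(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved_report(), sort_keys=True,
                       default=str).encode()).hexdigest()[:16]


_SECTIONS = {
    "mesh": {"subdivisions": "mesh_subdivisions",
             "radius_m": "mesh_radius_m"},
    "sensors": {"n_sensors": "n_sensors", "radius_m": "sensor_radius_m"},
    "preprocess": {"filter_low_hz": "filter_low_hz",
                   "filter_high_hz": "filter_high_hz",
                   "notch_hz": "notch_hz",
                   "rest_window_ms": "rest_window_ms",
                   "epoch_tmin_ms": "epoch_tmin_ms",
                   "epoch_tmax_ms": "epoch_tmax_ms",
                   "baseline_ms": "baseline_ms",
                   "ptp_limit_factor": "ptp_limit_factor"},
    "beamformer": {"cov_rest_window_ms": "cov_rest_window_ms",
                   "cov_post_window_ms": "cov_post_window_ms",
                   "projection": "projection"},
    "connectivity": {"bands": "fc_bands", "trim_ms": "trim_ms",
                     "fisher": "fisher"},
}


def validate_config(raw: dict | str | Path) -> PipelineConfig:
    """Resolve a (possibly empty) nested config mapping against defaults.

    Accepts a dict or a YAML path.  Unknown keys and out-of-range values are
    rejected with an itemized message; an empty config resolves every value
    to the study defaults (alpha 8-12 Hz, beta 15-29 Hz, TFCE E=0.5 H=2,
    cluster floor k>50, Bonferroni m=3, ...).
    """
    if isinstance(raw, (str, Path)):
        raw = yaml.safe_load(Path(raw).read_text()) or {}
    raw = dict(raw or {})
    kwargs: dict = {}
    errors: list[str] = []
    for top in ("seed", "outdir"):
        if top in raw:
            kwargs[top] = raw.pop(top)
    for section, mapping in _SECTIONS.items():
        sub = raw.pop(section, {}) or {}
        for key, val in sub.items():
            if key not in mapping:
                errors.append(f"unknown key {section}.{key}")
            else:
                if key in ("baseline_ms", "cov_rest_window_ms",
                           "cov_post_window_ms", "bands"):
                    val = tuple(val)
                kwargs[mapping[key]] = val
    sim_raw = raw.pop("simulation", {}) or {}
    stats_raw = raw.pop("stats", {}) or {}
    for key in raw:
        errors.append(f"unknown section or key {key!r}")
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    for key in list(sim_raw):
        if key not in sim_fields:
            errors.append(f"unknown key simulation.{key}")
            sim_raw.pop(key)
    tfce_fields = {f.name for f in dataclasses.fields(TFCEParams)}
    tfce_raw = {}
    for key in list(stats_raw):
        if key == "bonferroni_m":
            kwargs["bonferroni_m"] = stats_raw.pop(key)
        elif key in tfce_fields:
            tfce_raw[key] = stats_raw.pop(key)
        else:
            errors.append(f"unknown key stats.{key}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    if "target_vertices" in sim_raw:
        sim_raw["target_vertices"] = tuple(sim_raw["target_vertices"])
    if "bands" in sim_raw:
        sim_raw["bands"] = tuple(BAND_BY_NAME[b] for b in sim_raw["bands"])
    try:
        sim = SimulationConfig(**sim_raw)
        tfce = TFCEParams(**tfce_raw)
        cfg = PipelineConfig(simulation=sim, tfce=tfce, **kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    if "seed" in kwargs:
        cfg.simulation = replace(cfg.simulation, rng_seed=int(cfg.seed))
    return cfg


# ---------------------------------------------------------------------------
# shared context

@dataclass
class _Context:
    config: PipelineConfig
    outdir: Path
    space: SourceSpace
    sensors: object
    leadfield: object


def _build_context(config: PipelineConfig, outdir: str | Path | None = None
                   ) -> _Context:
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    space = make_cortical_mesh(subdivisions=config.mesh_subdivisions,
                               radius=config.mesh_radius_m)
    sensors = make_helmet_array(n_sensors=config.n_sensors,
                                radius=config.sensor_radius_m)
    leadfield = sphere_forward(space, sensors, normalize=True)
    return _Context(config, outdir, space, sensors, leadfield)


def default_layout(space: SourceSpace, leadfield
                   ) -> tuple[int, tuple[int, ...]]:
    """Deterministic seed / target placement on a synthetic mesh.

    The "S1" seed is the vertex with the strongest constrained lead field
    (well seen by the array); the connectivity target is a 10-vertex patch
    around the strongest-lead-field vertex at least a third of the mesh
    diameter away from the seed (a distinct "parietal" region).
    """
    colnorm = np.linalg.norm(leadfield.constrained, axis=0)
    seed = int(np.argmax(colnorm))
    dist = space.graph_distance(seed)
    min_dist = max(3, int(dist.max() / 3))
    candidates = np.nonzero(dist >= min_dist)[0]
    center = int(candidates[np.argmax(colnorm[candidates])])
    targets = tuple(int(v) for v in space.nearest_vertices(center, 10))
    return seed, targets


def _with_layout(ctx: _Context) -> SimulationConfig:
    sim = ctx.config.simulation
    if not sim.target_vertices:
        seed, targets = default_layout(ctx.space, ctx.leadfield)
        sim = replace(sim, seed_vertex=seed, target_vertices=targets)
    sim.validate_vertices(ctx.space.n_vertices)
    return sim


def _provenance(config: PipelineConfig, stage: str) -> dict:
    return {"stage": stage, "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.resolved_report()}


# ---------------------------------------------------------------------------
# stages

def stage_simulate(ctx: _Context) -> None:
    cfg = ctx.config
    sim = _with_layout(ctx)
    io.save_source_space(ctx.outdir / "source_space.h5", ctx.space)
    truths, sub_cfgs = draw_cohort_truths(sim)
    behav_tables = []
    for truth, sub_cfg in zip(truths, sub_cfgs):
        s = truth.subject_id
        src, _ = simulate_source_rest(sub_cfg, ctx.space, s)
        rng = subject_rng(sub_cfg, s, 10)
        rest = mix_to_sensors(src, ctx.leadfield, ctx.sensors,
                              noise_sd=sub_cfg.noise_sd, rng=rng)
        io.save_recording(ctx.outdir / f"rest_{s:02d}.h5", rest)
        evoked, events, _ = simulate_evoked_trials(sub_cfg, ctx.space,
                                                   ctx.leadfield,
                                                   ctx.sensors, s)
        io.save_recording(ctx.outdir / f"evoked_{s:02d}.h5", evoked)
        io.save_events(ctx.outdir / f"events_{s:02d}.csv", events)
        rng_b = subject_rng(sub_cfg, s, 2)
        behav_tables.append(simulate_behavior(
            truth.true_threshold_mm, truth.true_slope, rng=rng_b,
            subject_id=s))
        logger.info("simulated subject %d (rho=%.3f thr=%.2f mm)", s,
                    truth.true_env_corr[sim.bands[0].name],
                    truth.true_threshold_mm)
    behavior = pd.concat(behav_tables, ignore_index=True)
    behavior.to_csv(ctx.outdir / "behavior.csv", index=False)
    truth_rows = [dataclasses.asdict(t) for t in truths]
    io.save_json(ctx.outdir / "ground_truth.json",
                 {"subjects": truth_rows,
                  "seed_vertex": sim.seed_vertex,
                  "target_vertices": list(sim.target_vertices)})
    io.save_json(ctx.outdir / "provenance_simulate.json",
                 _provenance(cfg, "simulate"))


def _preprocess_recording(cfg: PipelineConfig,
                          rec: SensorRecording) -> SensorRecording:
    high = min(cfg.filter_high_hz, 0.45 * rec.sfreq)
    notch = cfg.notch_hz if (cfg.notch_hz or 0) < 0.45 * rec.sfreq else None
    return bandpass_notch(rec, cfg.filter_low_hz, high, notch)


def _auto_reject(cfg: PipelineConfig, epochs):
    ptp = (epochs.data.max(axis=2) - epochs.data.min(axis=2)).max(axis=1)
    limit = cfg.ptp_limit_factor * float(np.median(ptp))
    return reject_trials(epochs, limit)


def stage_preprocess(ctx: _Context) -> None:
    cfg = ctx.config
    n_sub = cfg.simulation.n_subjects
    qc = []
    for s in range(n_sub):
        rest = _preprocess_recording(
            cfg, io.load_recording(ctx.outdir / f"rest_{s:02d}.h5"))
        rest_ep, rep = _auto_reject(cfg, segment_rest(rest,
                                                      cfg.rest_window_ms))
        io.save_epochs(ctx.outdir / f"preproc_rest_{s:02d}.h5", rest_ep)
        qc_row = {"subject": s, "rest_rejected": rep.fraction_rejected}
        evoked = _preprocess_recording(
            cfg, io.load_recording(ctx.outdir / f"evoked_{s:02d}.h5"))
        events = io.load_events(ctx.outdir / f"events_{s:02d}.csv")
        for cond in ("SP", "PP"):
            ep = epoch_evoked(evoked, events, cfg.epoch_tmin_ms,
                              cfg.epoch_tmax_ms, condition=cond)
            ep = baseline_correct(ep, *cfg.baseline_ms)
            ep, rep = _auto_reject(cfg, ep)
            io.save_epochs(ctx.outdir / f"preproc_{cond.lower()}_{s:02d}.h5",
                           ep)
            qc_row[f"{cond.lower()}_rejected"] = rep.fraction_rejected
        qc.append(qc_row)
        logger.info("preprocessed subject %d (rejected: rest %.1f%% "
                    "SP %.1f%% PP %.1f%%)", s,
                    100 * qc_row["rest_rejected"],
                    100 * qc_row["sp_rejected"], 100 * qc_row["pp_rejected"])
    pd.DataFrame(qc).to_csv(ctx.outdir / "qc_rejection.csv", index=False)
    io.save_json(ctx.outdir / "provenance_preprocess.json",
                 _provenance(cfg, "preprocess"))


def _weights_for(ctx: _Context, epochs, window_ms) -> BeamformerWeights:
    lo = max(window_ms[0], float(epochs.times_ms[0]))
    hi = min(window_ms[1], float(epochs.times_ms[-1]))
    cov = compute_data_covariance(epochs, (lo, hi))
    reg = regularize_median_eig(cov)
    return lcmv_weights(ctx.leadfield, reg, ctx.space.normals,
                        projection=ctx.config.projection)


def stage_beamform(ctx: _Context) -> None:
    cfg = ctx.config
    for s in range(cfg.simulation.n_subjects):
        rest_ep = io.load_epochs(ctx.outdir / f"preproc_rest_{s:02d}.h5")
        w_rest = _weights_for(ctx, rest_ep, cfg.cov_rest_window_ms)
        io.save_matrix(ctx.outdir / f"weights_rest_{s:02d}.h5",
                       w_rest.weights,
                       provenance={**w_rest.regularization,
                                   "subject": s, "kind": "rest"})
        sp_ep = io.load_epochs(ctx.outdir / f"preproc_sp_{s:02d}.h5")
        pp_ep = io.load_epochs(ctx.outdir / f"preproc_pp_{s:02d}.h5")
        both = sp_ep.copy_with(
            np.concatenate([sp_ep.data, pp_ep.data], axis=0))
        w_sef = _weights_for(ctx, both, cfg.cov_post_window_ms)
        io.save_matrix(ctx.outdir / f"weights_sef_{s:02d}.h5", w_sef.weights,
                       provenance={**w_sef.regularization,
                                   "subject": s, "kind": "sef"})
    io.save_json(ctx.outdir / "provenance_beamform.json",
                 _provenance(cfg, "beamform"))


def _n20m_seed_scout(ctx: _Context, s: int) -> SeedDefinition:
    """FC seed: 10-vertex scout on the N20m activation peak (SP map)."""
    sp_ep = io.load_epochs(ctx.outdir / f"preproc_sp_{s:02d}.h5")
    w = BeamformerWeights(io.load_matrix(
        ctx.outdir / f"weights_sef_{s:02d}.h5"))
    src = apply_inverse(w, sp_ep)
    evoked = average_evoked(src)
    scout = define_roi_scout(evoked, src.times_ms,
                             COMPONENT_WINDOWS_MS["N20m"], ctx.space,
                             "N20m")
    return SeedDefinition(scout.vertices)


def stage_connectivity(ctx: _Context) -> None:
    cfg = ctx.config
    for s in range(cfg.simulation.n_subjects):
        seed_def = _n20m_seed_scout(ctx, s)
        rest_ep = io.load_epochs(ctx.outdir / f"preproc_rest_{s:02d}.h5")
        w = BeamformerWeights(io.load_matrix(
            ctx.outdir / f"weights_rest_{s:02d}.h5"))
        src = apply_inverse(w, rest_ep)
        for name in cfg.fc_bands:
            cmap = seed_fc_map(src, seed_def, BAND_BY_NAME[name],
                               trim_ms=cfg.trim_ms, fisher=cfg.fisher)
            io.save_connectivity_map(
                ctx.outdir / f"fc_{name}_{s:02d}.h5", cmap)
        logger.info("connectivity maps done for subject %d", s)
    io.save_json(ctx.outdir / "provenance_connectivity.json",
                 _provenance(cfg, "connectivity"))


def stage_gating(ctx: _Context) -> None:
    cfg = ctx.config
    tables = []
    for s in range(cfg.simulation.n_subjects):
        w = BeamformerWeights(io.load_matrix(
            ctx.outdir / f"weights_sef_{s:02d}.h5"))
        sp = apply_inverse(w, io.load_epochs(
            ctx.outdir / f"preproc_sp_{s:02d}.h5"))
        pp = apply_inverse(w, io.load_epochs(
            ctx.outdir / f"preproc_pp_{s:02d}.h5"))
        results = analyze_gating(sp, pp, ctx.space,
                                 shift_ms=cfg.simulation.pp_gap_ms,
                                 baseline_ms=cfg.baseline_ms)
        tables.append(gating_table(results, subject=s))
    gating = pd.concat(tables, ignore_index=True)
    gating.to_csv(ctx.outdir / "gating.csv", index=False)
    io.save_json(ctx.outdir / "provenance_gating.json",
                 _provenance(cfg, "gating"))


def stage_psychometrics(ctx: _Context) -> None:
    cfg = ctx.config
    behavior = pd.read_csv(ctx.outdir / "behavior.csv")
    fits = fit_cohort(behavior)
    fits.to_csv(ctx.outdir / "thresholds.csv", index=False)
    io.save_json(ctx.outdir / "provenance_psychometrics.json",
                 _provenance(cfg, "psychometrics"))


def stage_groupstats(ctx: _Context) -> None:
    cfg = ctx.config
    n_sub = cfg.simulation.n_subjects
    thresholds = pd.read_csv(ctx.outdir / "thresholds.csv")
    thresholds = thresholds.sort_values("subject")["threshold_mm"].to_numpy()
    gating = pd.read_csv(ctx.outdir / "gating.csv")
    adjacency = ctx.space.adjacency
    summary: dict = {"n_subjects": n_sub}
    for name in cfg.fc_bands:
        maps = np.stack([io.load_connectivity_map(
            ctx.outdir / f"fc_{name}_{s:02d}.h5").values
            for s in range(n_sub)])
        maps = np.nan_to_num(maps)
        res = permutation_fwe(maps, thresholds, adjacency, cfg.tfce,
                              rng_seed=cfg.seed)
        io.save_matrix(ctx.outdir / f"stat_t_{name}.h5", res.t)
        io.save_matrix(ctx.outdir / f"stat_tfce_{name}.h5", res.tfce)
        io.save_matrix(ctx.outdir / f"stat_pfwe_{name}.h5", res.p_fwe)
        clusters = cluster_filter(res.p_fwe, adjacency,
                                  alpha=cfg.tfce.alpha,
                                  k_min=cfg.tfce.k_min)
        clusters.insert(0, "band", name)
        clusters.to_csv(ctx.outdir / f"clusters_{name}.csv", index=False)
        band_summary = {"n_clusters": int(len(clusters))}
        if len(clusters):
            peak = int(clusters.iloc[0]["peak_vertex"])
            rho = spearman(maps[:, peak], thresholds,
                           n_comparisons=cfg.bonferroni_m)
            band_summary["peak_vertex"] = peak
            band_summary["peak_spearman_r"] = rho.statistic
            band_summary["peak_spearman_p"] = rho.p
        summary[f"fc_{name}"] = band_summary
    # SP vs PP amplitudes and gating-performance correlations
    sef_tests, gating_corr = {}, {}
    for comp in COMPONENT_WINDOWS_MS:
        sub = gating[gating["component"] == comp].sort_values("subject")
        if len(sub) >= 5:
            wt = wilcoxon_signed_rank(sub["sp_amp"].to_numpy(),
                                      sub["pp_amp"].to_numpy(),
                                      n_comparisons=cfg.bonferroni_m)
            sef_tests[comp] = {"W": wt.statistic, "p": wt.p,
                               "p_bonferroni": wt.p_bonferroni}
        rho = spearman(sub["ratio"].to_numpy(), thresholds,
                       n_comparisons=cfg.bonferroni_m)
        gating_corr[comp] = {"R": rho.statistic, "p": rho.p,
                             "p_bonferroni": rho.p_bonferroni}
    summary["sef_sp_vs_pp"] = sef_tests
    summary["gating_vs_threshold"] = gating_corr
    io.save_json(ctx.outdir / "group_summary.json", summary)
    io.save_json(ctx.outdir / "provenance_groupstats.json",
                 _provenance(cfg, "groupstats"))


_STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "beamform": stage_beamform,
    "connect": stage_connectivity,
    "gating": stage_gating,
    "psychometric": stage_psychometrics,
    "groupstats": stage_groupstats,
}

STAGE_ORDER = ("simulate", "preprocess", "beamform", "connect", "gating",
               "psychometric", "groupstats")


def run_stage(config: PipelineConfig, stage: str,
              outdir: str | Path | None = None) -> Path:
    ctx = _build_context(config, outdir)
    try:
        _STAGES[stage](ctx)
    except Exception as exc:
        (ctx.outdir / "INCOMPLETE").write_text(
            f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"[{stage}] {exc}") from exc
    return ctx.outdir


def run_pipeline(config: PipelineConfig,
                 outdir: str | Path | None = None) -> Path:
    """Execute every stage in order; partial outputs are flagged on error."""
    ctx = _build_context(config, outdir)
    for stage in STAGE_ORDER:
        logger.info("=== stage %s ===", stage)
        try:
            _STAGES[stage](ctx)
        except Exception as exc:
            (ctx.outdir / "INCOMPLETE").write_text(
                f"stage {stage} failed: {exc}\n")
            raise RuntimeError(f"[{stage}] {exc}") from exc
    flag = ctx.outdir / "INCOMPLETE"
    if flag.exists():
        flag.unlink()
    io.save_json(ctx.outdir / "provenance_run.json",
                 _provenance(config, "run-all"))
    return ctx.outdir
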