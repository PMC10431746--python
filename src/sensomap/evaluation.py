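"""Recovery and calibration experiments on synthetic ground truth.

Each function runs a self-contained, seeded study at desk scale and returns
the measured quantities; the test suite asserts on them and the acceptance
script reports them.  Problem sizes (mesh resolution, channel counts,
durations, permutation counts) are the package's desk-scale study
conditions, documented in the methods note.
"""

from __future__ import annotations



import numpy as np

from .beamformer import (apply_inverse, compute_data_covariance,
                         lcmv_weights, neural_activity_index,
                         regularize_median_eig)
from .connectivity import ALPHA, SeedDefinition, aec_max_null, seed_fc_map
from .containers import EpochSet
from .forward import LeadField, dipole_field, sphere_forward
from .gating import analyze_gating
from .mesh import SourceSpace, make_cortical_mesh
from .pipeline import PipelineConfig
from .preprocess import (bandpass_notch, baseline_correct, epoch_evoked,
                         segment_rest)
from .psychometrics import fit_psychometric
from .sensors import SensorArray, make_helmet_array
from .simulate import (SimulationConfig, mix_to_sensors, simulate_behavior,
                       simulate_evoked_trials, simulate_source_rest,
                       simulate_fc_cohort_maps, subject_rng)
from .stats import TFCEParams, permutation_fwe

# ---------------------------------------------------------------------------
# forward model


def forward_oracle_case() -> dict:
    """Reference dipole/sensor geometry for the forward-field comparison.

    A tangential dipole at 0.6 conductor radii and five sensors outside;
    the matching quadrature reference lives with the test oracles.
    """
    R = 0.09
    r_dip = np.array([0.02, -0.01, 0.045])
    q_dir = np.cross(r_dip, [0.0, 0.0, 1.0])
    q = 1e-8 * q_dir / np.linalg.norm(q_dir)
    sensors = np.array([[0.0, 0.05, 0.11], [0.09, 0.02, 0.08],
                        [-0.06, 0.08, 0.07], [0.01, -0.1, 0.09],
                        [0.1, 0.1, 0.02]])
    B = dipole_field(r_dip, q, sensors)
    q_rad = 1e-8 * r_dip / np.linalg.norm(r_dip)
    B_radial = dipole_field(r_dip, q_rad, sensors)
    return {"R": R, "r_dip": r_dip, "q": q, "sensors": sensors,
            "B_sarvas": B, "B_radial_dipole": B_radial}


# ---------------------------------------------------------------------------
# beamformer localization


def _chain_geometry(subdivisions: int, n_sensors: int
                    ) -> tuple[SourceSpace, SensorArray, LeadField]:
    space = make_cortical_mesh(subdivisions=subdivisions)
    sensors = make_helmet_array(n_sensors=n_sensors)
    leadfield = sphere_forward(space, sensors, normalize=True)
    return space, sensors, leadfield


def localization_errors(n_seeds: int = 10, subdivisions: int = 4,
                        n_sensors: int = 64, snr: float = 5.0,
                        sfreq: float = 250.0, duration_s: float = 20.0,
                        base_seed: int = 0) -> list[int]:
    """Edge distance between a planted oscillating dipole and the peak of
    the beamformer's noise-normalized output power, per seed."""
    space, sensors, leadfield = _chain_geometry(subdivisions, n_sensors)
    n = int(duration_s * sfreq)
    errors = []
    for k in range(n_seeds):
        rng = np.random.default_rng([base_seed, k])
        v_true = int(rng.integers(space.n_vertices))
        carrier = np.sin(2 * np.pi * 11 * np.arange(n) / sfreq
                         + rng.uniform(0, 2 * np.pi))
        src = carrier * (1 + 0.3 * rng.standard_normal(n))
        sig = np.outer(leadfield.constrained[:, v_true], src)
        noise_sd = sig.std() / snr
        data = sig + rng.normal(0.0, noise_sd, size=sig.shape)
        n_ep = 10
        ep = EpochSet(data.reshape(sensors.n_channels, n_ep, -1)
                      .transpose(1, 0, 2).copy(), sfreq, 0.0, "rest")
        cov = compute_data_covariance(ep)
        w = lcmv_weights(leadfield, regularize_median_eig(cov),
                         space.normals)
        nai = neural_activity_index(w, cov, noise_variance=noise_sd ** 2)
        v_est = int(np.argmax(nai))
        errors.append(int(space.graph_distance(v_true)[v_est]))
    return errors


# ---------------------------------------------------------------------------
# envelope-correlation recovery through the full chain


def _chain_layout(space: SourceSpace, leadfield: LeadField
                  ) -> tuple[int, int]:
    colnorm = np.linalg.norm(leadfield.constrained, axis=0)
    seed_v = int(np.argmax(colnorm))
    dist = space.graph_distance(seed_v)
    cand = np.nonzero(dist >= dist.max() // 2)[0]
    target = int(cand[np.argmax(colnorm[cand])])
    return seed_v, target


def aec_chain_recovery(levels=(0.0, 0.3, 0.6, 0.9), n_seeds: int = 25,
                       subdivisions: int = 2, n_sensors: int = 48,
                       sfreq: float = 250.0, duration_s: float = 120.0,
                       base_seed: int = 0) -> dict[float, np.ndarray]:
    """Planted vs recovered envelope correlation through
    simulate -> mix -> beamform -> orthogonalized seed AEC.

    Returns per-level arrays of the target-patch mean AEC, one per seed.
    """
    space, sensors, leadfield = _chain_geometry(subdivisions, n_sensors)
    seed_v, target = _chain_layout(space, leadfield)
    seed_patch = space.nearest_vertices(seed_v, 10)
    target_patch = space.nearest_vertices(target, 10)
    out: dict[float, np.ndarray] = {}
    for rho in levels:
        vals = []
        for k in range(n_seeds):
            cfg = SimulationConfig(
                sfreq=sfreq, rest_duration=duration_s, bands=(ALPHA,),
                seed_vertex=seed_v, target_vertices=(target,),
                planted_env_corr=rho, rng_seed=base_seed + k)
            src, _ = simulate_source_rest(cfg, space, 0)
            rec = mix_to_sensors(src, leadfield, sensors,
                                 noise_sd=cfg.noise_sd,
                                 rng=subject_rng(cfg, 0, 10))
            ep = segment_rest(rec, 2000.0)
            cov = compute_data_covariance(ep, (0.0, 2000.0))
            w = lcmv_weights(leadfield, regularize_median_eig(cov),
                             space.normals)
            cmap = seed_fc_map(apply_inverse(w, ep),
                               SeedDefinition(seed_patch), ALPHA)
            vals.append(float(np.nanmean(cmap.values[target_patch])))
        out[rho] = np.array(vals)
    return out


def leakage_null_experiment(subdivisions: int = 2, n_sensors: int = 48,
                            sfreq: float = 250.0, duration_s: float = 60.0,
                            n_permutations: int = 50, base_seed: int = 0
                            ) -> dict[str, float]:
    """One-source world: does orthogonalized AEC stay inside the
    epoch-mispairing null everywhere off the seed?"""
    space, sensors, leadfield = _chain_geometry(subdivisions, n_sensors)
    seed_v, _ = _chain_layout(space, leadfield)
    seed_patch = space.nearest_vertices(seed_v, 10)
    cfg = SimulationConfig(sfreq=sfreq, rest_duration=duration_s,
                           bands=(ALPHA,), seed_vertex=seed_v,
                           target_vertices=(), planted_env_corr=0.6,
                           patch_size=1, background_amp=0.0, noise_sd=0.5,
                           rng_seed=base_seed)
    src, _ = simulate_source_rest(cfg, space, 0)
    rec = mix_to_sensors(src, leadfield, sensors, noise_sd=cfg.noise_sd,
                         rng=subject_rng(cfg, 0, 10))
    ep = segment_rest(rec, 2000.0)
    cov = compute_data_covariance(ep, (0.0, 2000.0))
    w = lcmv_weights(leadfield, regularize_median_eig(cov), space.normals)
    src_ep = apply_inverse(w, ep)
    seed_def = SeedDefinition(seed_patch)
    m_orth = seed_fc_map(src_ep, seed_def, ALPHA)
    m_naive = seed_fc_map(src_ep, seed_def, ALPHA, orthogonalize=False)
    other = np.setdiff1d(np.arange(space.n_vertices), seed_patch)
    null = aec_max_null(src_ep, seed_def, ALPHA,
                        n_permutations=n_permutations,
                        rng=np.random.default_rng([base_seed, 1]))
    return {"orth_max": float(np.nanmax(np.abs(m_orth.values[other]))),
            "naive_max": float(np.nanmax(np.abs(m_naive.values[other]))),
            "null_95": float(np.percentile(null, 95))}


# ---------------------------------------------------------------------------
# gating recovery


def gating_recovery(levels=(0.0, 0.25, 0.5, 0.75, 1.0),
                    n_trials: int = 300, subdivisions: int = 2,
                    n_sensors: int = 48, sfreq: float = 500.0,
                    base_seed: int = 1) -> dict[float, float]:
    """Planted N20m gating factor vs the ratio recovered by the full
    evoked pipeline (epoch, baseline, beamform, subtract, rectify, peak)."""
    space, sensors, leadfield = _chain_geometry(subdivisions, n_sensors)
    colnorm = np.linalg.norm(leadfield.constrained, axis=0)
    seed_v = int(np.argmax(colnorm))
    out = {}
    for g in levels:
        cfg = SimulationConfig(
            sfreq=sfreq, n_sp_trials=n_trials, n_pp_trials=n_trials,
            seed_vertex=seed_v,
            planted_gating={"N20m": g, "P35m": 0.6, "P60m": 0.7},
            rng_seed=base_seed)
        rec, events, _ = simulate_evoked_trials(cfg, space, leadfield,
                                                sensors, 0)
        rec = bandpass_notch(rec, 0.5, min(100.0, 0.45 * sfreq), None)
        eps = {}
        for cond in ("SP", "PP"):
            ep = epoch_evoked(rec, events, -1500.0, 2500.0, condition=cond)
            eps[cond] = baseline_correct(ep)
        both = eps["SP"].copy_with(
            np.concatenate([eps["SP"].data, eps["PP"].data]))
        cov = compute_data_covariance(both, (0.0, 2500.0))
        w = lcmv_weights(leadfield, regularize_median_eig(cov),
                         space.normals)
        results = analyze_gating(apply_inverse(w, eps["SP"]),
                                 apply_inverse(w, eps["PP"]), space)
        out[g] = float({r.component: r.ratio
                        for r in results}["N20m"])
    return out


# ---------------------------------------------------------------------------
# psychometrics


def psychometric_calibration(n_replicates: int = 100,
                             truth_mm: float = 2.5, slope: float = 3.0,
                             base_seed: int = 42) -> dict[str, float]:
    """Threshold-recovery bias of the logistic fit at the task design
    (10 distances x 16 trials)."""
    rng = np.random.default_rng(base_seed)
    errors = []
    for _ in range(n_replicates):
        table = simulate_behavior(truth_mm, slope, rng=rng)
        fit = fit_psychometric(table)
        errors.append(fit.threshold_mm - truth_mm)
    errors = np.array(errors)
    return {"mean_bias_mm": float(errors.mean()),
            "mean_abs_error_mm": float(np.abs(errors).mean()),
            "sd_mm": float(errors.std())}


# ---------------------------------------------------------------------------
# group statistics


def fwe_null_rate(n_cohorts: int = 100, n_subjects: int = 20,
                  n_permutations: int = 500, subdivisions: int = 3,
                  base_seed: int = 1000) -> float:
    """Family-wise false-positive rate on exact-null cohorts."""
    space = make_cortical_mesh(subdivisions=subdivisions)
    target = space.nearest_vertices(50, 30)
    params = TFCEParams(n_permutations=n_permutations, k_min=10)
    hits = 0
    for c in range(n_cohorts):
        rng = np.random.default_rng(base_seed + c)
        maps, thr, _ = simulate_fc_cohort_maps(space, n_subjects, target,
                                               rng, coupling_slope=0.0)
        res = permutation_fwe(maps, thr, space.adjacency, params,
                              rng_seed=c)
        hits += bool((res.p_fwe < 0.05).any())
    return hits / n_cohorts


def fwe_power(n_replicates: int = 25, n_subjects: int = 20,
              n_permutations: int = 500, subdivisions: int = 3,
              coupling_slope: float = -2.0, base_seed: int = 2000) -> float:
    """Detection rate of the planted connectivity-behavior coupling."""
    space = make_cortical_mesh(subdivisions=subdivisions)
    target = space.nearest_vertices(50, 30)
    params = TFCEParams(n_permutations=n_permutations, k_min=10)
    hits = 0
    for c in range(n_replicates):
        rng = np.random.default_rng(base_seed + c)
        maps, thr, _ = simulate_fc_cohort_maps(
            space, n_subjects, target, rng, coupling_slope=coupling_slope)
        res = permutation_fwe(maps, thr, space.adjacency, params,
                              rng_seed=c)
        hits += bool((res.p_fwe[target] < 0.05).any())
    return hits / n_replicates


# ---------------------------------------------------------------------------
# demo pipeline


def demo_config(seed: int = 0, n_subjects: int = 8,
                outdir: str = "demo_out") -> PipelineConfig:
    """Small but complete cohort configuration (minutes on one CPU)."""
    sim = SimulationConfig(
        n_subjects=n_subjects, sfreq=250.0, rest_duration=40.0,
        n_sp_trials=30, n_pp_trials=30, isi_range_s=(1.5, 2.0),
        rng_seed=seed)
    cfg = PipelineConfig(
        seed=seed, outdir=outdir, mesh_subdivisions=2, n_sensors=32,
        simulation=sim, filter_high_hz=80.0, notch_hz=None,
        epoch_tmin_ms=-400.0, epoch_tmax_ms=700.0,
        cov_rest_window_ms=(0.0, 2000.0), cov_post_window_ms=(0.0, 700.0),
        tfce=TFCEParams(n_permutations=300, k_min=5))
    return cfg
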