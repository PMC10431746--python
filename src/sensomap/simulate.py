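"""Synthetic cohort generator with recoverable ground truth.

Every downstream stage is validated against data whose generating values are
known: band-limited cortical oscillators with a planted amplitude-envelope
correlation, stereotyped evoked responses with a planted paired-pulse
attenuation, binomial psychometric responses from a known logistic curve,
and a cohort in which per-subject connectivity linearly predicts the
discrimination threshold (negative coupling: stronger connectivity, lower
threshold).

Envelope model.  An active vertex carries ``x(t) = E(t) * c(t)`` where the
carrier ``c`` is a unit-amplitude oscillator frequency-modulated inside the
band and ``E = exp(a*z_shared + b*z_own)`` is a log-normal envelope built
from smoothed, standardized Gaussian processes.  Because the carrier has
constant amplitude and never leaves the pass band, the Hilbert envelope of
``x`` after band filtering *is* ``E``, so the closed-form weight
``a^2 = ln(1 + rho*(exp(s^2) - 1))`` (with ``a^2 + b^2 = s^2``) plants the
pairwise envelope correlation ``rho`` exactly; a fluctuating carrier
envelope would otherwise cap the measurable correlation well below one
regardless of ``rho``.

Ground truth is recorded from the generating parameters before any noise is
injected and is never recomputed from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from scipy.ndimage import gaussian_filter1d

from .connectivity import ALPHA, BETA, BandSpec
from .containers import SensorRecording, SourceTimeCourses
from .forward import LeadField
from .gating import NOMINAL_LATENCIES_MS
from .mesh import SourceSpace
from .sensors import SensorArray

TWO_POINT = "two_point"
ONE_POINT = "one_or_uncertain"

#: pin separations of the discrimination task (mm); 0 = single pin
TASK_DISTANCES_MM: tuple[float, ...] = (
    0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)

# stream codes for per-subject seed derivation
_STREAM_REST, _STREAM_EVOKED, _STREAM_BEHAVIOR, _STREAM_COHORT = 0, 1, 2, 3

#: Gabor-like deflection shapes: (sigma_ms, cycle_hz, sign)
_SEF_SHAPES: dict[str, tuple[float, float, float]] = {
    "N20m": (2.5, 40.0, +1.0),
    "P35m": (5.0, 22.0, -1.0),
    "P60m": (9.0, 12.0, +1.0),
}


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic cohort.

    Defaults mirror the emulated acquisition: 1 kHz sampling, 5 min of
    resting state segmented into 2 s epochs, ~300 stimulations per
    condition, alpha/beta oscillators, a 100 ms paired-pulse gap, 10 task
    distances x 16 trials.  ``rng_seed`` fully determines every output.
    """

    n_subjects: int = 42
    sfreq: float = 1000.0
    rest_duration: float = 300.0
    n_sp_trials: int = 300
    n_pp_trials: int = 300
    bands: tuple[BandSpec, ...] = (ALPHA, BETA)
    seed_vertex: int = 0
    target_vertices: tuple[int, ...] = ()
    planted_env_corr: float = 0.6
    patch_size: int = 10              # coherent vertices per active source
    planted_gating: dict[str, float] = field(default_factory=lambda: {
        "N20m": 0.5, "P35m": 0.6, "P60m": 0.7})
    psychometric_slope: float = 3.0       # 1/mm
    threshold_intercept_mm: float = 3.6   # mm, at zero connectivity
    coupling_slope: float = -2.0          # mm per unit envelope correlation
    threshold_noise_sd: float = 0.3       # mm
    env_corr_range: tuple[float, float] = (0.2, 0.8)
    noise_sd: float = 1.0                 # sensor units (white)
    background_amp: float = 0.3           # inactive-vertex source rms
    evoked_amp: float = 10.0              # evoked dipole amplitude
    isi_range_s: tuple[float, float] = (3.5, 4.5)
    pp_gap_ms: float = 100.0
    envelope_log_sd: float = 0.5          # s in E = exp(N(0, s^2))
    envelope_smooth_ms: float = 150.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.rest_duration <= 0:
            raise ValueError("rest_duration must be positive")
        if not 0.0 <= self.planted_env_corr <= 1.0:
            raise ValueError("planted_env_corr must lie in [0, 1]")
        if any(g < 0 for g in self.planted_gating.values()):
            raise ValueError("planted gating ratios must be >= 0")
        if self.seed_vertex in self.target_vertices:
            raise ValueError("seed vertex may not be a target vertex "
                             "(degenerate correlation)")
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric slope must be positive")

    def validate_vertices(self, n_vertices: int) -> None:
        idx = (self.seed_vertex, *self.target_vertices)
        if any(v < 0 or v >= n_vertices for v in idx):
            raise ValueError("vertex index out of range for this mesh")


@dataclass(frozen=True)
class SubjectGroundTruth:
    """Generating values, recorded before noise injection; immutable."""

    subject_id: int
    true_seed_vertex: int
    true_env_corr: dict[str, float]          # band name -> planted rho
    true_gating: dict[str, float]            # component -> planted ratio
    true_threshold_mm: float
    true_slope: float


def subject_rng(config: SimulationConfig, subject_id: int,
                stream: int) -> np.random.Generator:
    """Independent, reproducible per-subject / per-stream generator."""
    return np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, subject_id, stream]))


def envelope_weights(rho: float, log_sd: float) -> tuple[float, float]:
    """Closed-form shared/independent weights hitting envelope corr rho."""
    s2 = log_sd ** 2
    a2 = np.log1p(rho * np.expm1(s2))
    return float(np.sqrt(a2)), float(np.sqrt(max(s2 - a2, 0.0)))


def _smooth_standard_gaussian(rng: np.random.Generator, n: int,
                              sigma_samples: float) -> np.ndarray:
    z = gaussian_filter1d(rng.standard_normal(n), sigma_samples,
                          mode="wrap")
    return (z - z.mean()) / z.std()


def _band_noise(rng: np.random.Generator, n: int, sfreq: float,
                band: BandSpec) -> np.ndarray:
    """Unit-rms band-limited noise (FFT brick-wall with soft edges)."""
    x = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    gain = np.zeros_like(f)
    inside = (f >= band.low_hz) & (f <= band.high_hz)
    gain[inside] = 1.0
    edge = max(0.5, 0.1 * (band.high_hz - band.low_hz))
    rise = (f >= band.low_hz - edge) & (f < band.low_hz)
    fall = (f > band.high_hz) & (f <= band.high_hz + edge)
    gain[rise] = np.cos(np.pi * (band.low_hz - f[rise]) / edge / 2) ** 2
    gain[fall] = np.cos(np.pi * (f[fall] - band.high_hz) / edge / 2) ** 2
    y = np.fft.irfft(np.fft.rfft(x) * gain, n)
    return y / y.std()


def _unit_amplitude_carrier(rng: np.random.Generator, n: int, sfreq: float,
                            band: BandSpec) -> np.ndarray:
    """Unit-amplitude oscillator whose instantaneous frequency wanders
    inside the band (smooth FM around the band center).

    Because the amplitude is constant and the instantaneous frequency never
    leaves the pass band, band-pass filtering passes the signal essentially
    unchanged and its Hilbert envelope is flat: the envelope of
    ``E(t) * carrier`` is ``E`` itself.
    """
    center = 0.5 * (band.low_hz + band.high_hz)
    dev = 0.3 * (band.high_hz - band.low_hz) / 2.0
    z = _smooth_standard_gaussian(rng, n, 0.1 * sfreq)
    f_inst = center + dev * np.clip(z, -3.0, 3.0)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / sfreq
    phase += rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(phase)


def simulate_source_rest(config: SimulationConfig, space: SourceSpace,
                         subject_id: int = 0,
                         ) -> tuple[SourceTimeCourses, SubjectGroundTruth]:
    """Resting-state cortical sources with a planted envelope correlation.

    The seed vertex and every target vertex share, per band, a log-normal
    envelope component weighted to give pairwise envelope correlation
    ``planted_env_corr``.  Each active source is a compact cortical patch
    of ``patch_size`` vertices sharing one amplitude envelope but carrying
    independent carrier phases: scout averaging sees a common envelope, yet
    there is no zero-lag coherence for the minimum-variance filter to
    cancel (perfectly coherent patches would be suppressed by the
    beamformer's correlated-source cancellation).  All remaining vertices
    carry independent band-limited noise at ``background_amp`` rms.
    """
    config.validate_vertices(space.n_vertices)
    rng = subject_rng(config, subject_id, _STREAM_REST)
    n = int(round(config.rest_duration * config.sfreq))
    data = np.zeros((space.n_vertices, n))
    centers = [config.seed_vertex, *config.target_vertices]
    patches = {v: space.nearest_vertices(v, config.patch_size)
               for v in centers}
    sigma = config.envelope_smooth_ms / 1000.0 * config.sfreq
    a, b = envelope_weights(config.planted_env_corr, config.envelope_log_sd)
    for band in config.bands:
        z_shared = _smooth_standard_gaussian(rng, n, sigma)
        for v in centers:
            z_own = _smooth_standard_gaussian(rng, n, sigma)
            env = np.exp(a * z_shared + b * z_own)
            for member in patches[v]:
                carrier = _unit_amplitude_carrier(rng, n, config.sfreq,
                                                  band)
                x = env * carrier
                data[member] += x / x.std()
    active = np.unique(np.concatenate(list(patches.values())))
    inactive = np.setdiff1d(np.arange(space.n_vertices), active)
    for v in inactive:
        for band in config.bands:
            data[v] += config.background_amp * _band_noise(
                rng, n, config.sfreq, band)
    truth = SubjectGroundTruth(
        subject_id=subject_id, true_seed_vertex=config.seed_vertex,
        true_env_corr={b.name: config.planted_env_corr
                       for b in config.bands},
        true_gating=dict(config.planted_gating),
        true_threshold_mm=np.nan, true_slope=config.psychometric_slope)
    return SourceTimeCourses(data, config.sfreq), truth


def mix_to_sensors(source_tc: SourceTimeCourses, leadfield: LeadField,
                   sensors: SensorArray, noise_sd: float = 0.0,
                   rng: np.random.Generator | None = None) -> SensorRecording:
    """Linear forward mixing plus white Gaussian sensor noise."""
    L = leadfield.constrained
    if L is None:
        raise ValueError("lead field must be orientation-constrained")
    if L.shape[1] != source_tc.n_vertices:
        raise ValueError("lead-field column count != modeled vertices")
    out = L @ source_tc.data
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return SensorRecording(out, source_tc.sfreq, sensors)


def sef_waveform(times_ms: np.ndarray,
                 component_scale: dict[str, float] | None = None,
                 amplitude: float = 1.0) -> np.ndarray:
    """Stereotyped S1 response: three Gabor-like deflections.

    Component peaks sit at 22/33/58 ms; ``component_scale`` scales each
    deflection individually (used to plant gating ratios).
    """
    t = np.asarray(times_ms, dtype=float)
    out = np.zeros_like(t)
    for comp, mu in NOMINAL_LATENCIES_MS.items():
        sigma, f, sign = _SEF_SHAPES[comp]
        scale = 1.0 if component_scale is None else component_scale.get(
            comp, 1.0)
        out += (sign * scale
                * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
                * np.cos(2 * np.pi * f * (t - mu) / 1000.0))
    return amplitude * out


def simulate_evoked_trials(config: SimulationConfig, space: SourceSpace,
                           leadfield: LeadField, sensors: SensorArray,
                           subject_id: int = 0,
                           ) -> tuple[SensorRecording, pd.DataFrame,
                                      SubjectGroundTruth]:
    """Continuous evoked recording with randomly interleaved SP/PP trials.

    SP trials place the stereotyped waveform at the trigger; PP trials add a
    second copy at +``pp_gap_ms`` with each deflection scaled by the planted
    gating ratio.  The event table lists the (first) trigger sample and the
    condition label.
    """
    config.validate_vertices(space.n_vertices)
    if any(g < 0 for g in config.planted_gating.values()):
        raise ValueError("planted gating ratios must be >= 0")
    rng = subject_rng(config, subject_id, _STREAM_EVOKED)
    sfreq = config.sfreq
    n_trials = config.n_sp_trials + config.n_pp_trials
    labels = np.array(["SP"] * config.n_sp_trials
                      + ["PP"] * config.n_pp_trials)
    rng.shuffle(labels)
    isis = rng.uniform(*config.isi_range_s, size=n_trials)
    onsets_s = 2.0 + np.cumsum(isis) - isis[0]
    n_total = int(np.ceil((onsets_s[-1] + 3.0) * sfreq))

    # single-vertex evoked source: only the seed (S1) vertex is active
    wave_t = np.arange(0, int(0.1 * sfreq)) * 1000.0 / sfreq  # 100 ms
    sp_wave = sef_waveform(wave_t, amplitude=config.evoked_amp)
    pp_second = sef_waveform(wave_t, component_scale=config.planted_gating,
                             amplitude=config.evoked_amp)
    gap = int(round(config.pp_gap_ms * sfreq / 1000.0))
    src = np.zeros(n_total)
    samples = np.round(onsets_s * sfreq).astype(int)
    for s, lab in zip(samples, labels):
        src[s:s + len(sp_wave)] += sp_wave
        if lab == "PP":
            src[s + gap:s + gap + len(pp_second)] += pp_second

    L = leadfield.constrained
    if L is None:
        raise ValueError("lead field must be orientation-constrained")
    data = np.outer(L[:, config.seed_vertex], src)
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)
    events = pd.DataFrame({"sample": samples, "condition": labels})
    truth = SubjectGroundTruth(
        subject_id=subject_id, true_seed_vertex=config.seed_vertex,
        true_env_corr={b.name: config.planted_env_corr
                       for b in config.bands},
        true_gating=dict(config.planted_gating),
        true_threshold_mm=np.nan, true_slope=config.psychometric_slope)
    return SensorRecording(data, sfreq, sensors), events, truth


def simulate_behavior(threshold_mm: float, slope: float,
                      distances: tuple[float, ...] = TASK_DISTANCES_MM,
                      trials_per_distance: int = 16,
                      rng: np.random.Generator | int | None = None,
                      subject_id: int | str = 0) -> pd.DataFrame:
    """Bernoulli two-point responses from a logistic psychometric curve.

    ``P(two_point | d) = logistic(slope * (d - threshold_mm))`` — exactly
    0.5 at the threshold.  Distances must be non-negative and non-empty.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if len(distances) == 0:
        raise ValueError("empty distance list")
    if any(d < 0 for d in distances):
        raise ValueError("distances must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    from scipy.special import expit
    rows = []
    for d in distances:
        p = expit(slope * (d - threshold_mm))
        resp = rng.random(trials_per_distance) < p
        for k, r in enumerate(resp):
            rows.append({"subject": subject_id, "distance_mm": d,
                         "trial": k, "response":
                         TWO_POINT if r else ONE_POINT})
    return pd.DataFrame(rows)


@dataclass
class CohortBundle:
    """Per-subject synthetic data plus the generating truth table."""

    config: SimulationConfig
    truths: list[SubjectGroundTruth]
    behavior: pd.DataFrame                       # all subjects pooled
    subject_configs: list[SimulationConfig]

    @property
    def truth_table(self) -> pd.DataFrame:
        rows = []
        for t in self.truths:
            row = {"subject": t.subject_id,
                   "true_threshold_mm": t.true_threshold_mm,
                   "true_slope": t.true_slope,
                   "seed_vertex": t.true_seed_vertex}
            row.update({f"env_corr_{k}": v
                        for k, v in t.true_env_corr.items()})
            row.update({f"gating_{k}": v for k, v in t.true_gating.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def draw_cohort_truths(config: SimulationConfig
                       ) -> tuple[list[SubjectGroundTruth],
                                  list[SimulationConfig]]:
    """Draw per-subject planted values for a cohort.

    Per-subject envelope correlation is uniform on ``env_corr_range``; the
    true threshold is ``intercept + coupling_slope * env_corr + N(0, sd)``
    (negative slope: strong connectivity, better performance), floored at
    0.3 mm.  Recorded before any signal is generated.
    """
    if config.n_subjects < 8:
        raise ValueError("cohort needs at least 8 subjects")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, _STREAM_COHORT]))
    truths, subject_configs = [], []
    for s in range(config.n_subjects):
        rho = float(rng.uniform(*config.env_corr_range))
        thr = (config.threshold_intercept_mm
               + config.coupling_slope * rho
               + rng.normal(0.0, config.threshold_noise_sd))
        thr = float(max(thr, 0.3))
        sub_cfg = replace(config, planted_env_corr=rho)
        truths.append(SubjectGroundTruth(
            subject_id=s, true_seed_vertex=config.seed_vertex,
            true_env_corr={b.name: rho for b in config.bands},
            true_gating=dict(config.planted_gating),
            true_threshold_mm=thr, true_slope=config.psychometric_slope))
        subject_configs.append(sub_cfg)
    return truths, subject_configs


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Cohort bundle: truths, per-subject configs, pooled behavior table.

    Heavy sensor-level recordings are generated on demand from the
    per-subject configs (see ``simulate_source_rest`` /
    ``simulate_evoked_trials``) so cohorts of any size stay cheap to draw.
    """
    truths, sub_cfgs = draw_cohort_truths(config)
    tables = []
    for t in truths:
        rng = subject_rng(config, t.subject_id, _STREAM_BEHAVIOR)
        tables.append(simulate_behavior(
            t.true_threshold_mm, t.true_slope, rng=rng,
            subject_id=t.subject_id))
    behavior = pd.concat(tables, ignore_index=True)
    return CohortBundle(config=config, truths=truths, behavior=behavior,
                        subject_configs=sub_cfgs)


def smooth_vertex_noise(space: SourceSpace, rng: np.random.Generator,
                        n_maps: int = 1, n_smooth: int = 2) -> np.ndarray:
    """Spatially smooth unit-variance noise maps, (n_maps, n_vertices)."""
    adj = space.adjacency.astype(float)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    x = rng.standard_normal((n_maps, space.n_vertices))
    for _ in range(n_smooth):
        x = (x + x @ adj.T) / (1.0 + deg)[None, :]
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    return x


def simulate_fc_cohort_maps(space: SourceSpace, n_subjects: int,
                            target_vertices: np.ndarray,
                            rng: np.random.Generator,
                            coupling_slope: float = -2.0,
                            intercept_mm: float = 3.6,
                            threshold_noise_sd: float = 0.3,
                            map_noise_sd: float = 0.08,
                            fc_range: tuple[float, float] = (0.2, 0.8),
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map-level cohort for group-statistics studies.

    Emits per-subject connectivity maps (smooth spatial noise plus a target
    patch whose height is the subject's connectivity strength) and the
    coupled behavioral covariate.  With ``coupling_slope = 0`` the cohort is
    an exact null for FWE-control studies.

    Returns ``(maps (S, V), thresholds (S,), fc (S,))``.
    """
    target_vertices = np.asarray(target_vertices, dtype=int)
    fc = rng.uniform(*fc_range, size=n_subjects)
    thresholds = (intercept_mm + coupling_slope * fc
                  + rng.normal(0.0, threshold_noise_sd, size=n_subjects))
    bump = np.zeros(space.n_vertices)
    bump[target_vertices] = 1.0
    maps = map_noise_sd * smooth_vertex_noise(space, rng,
                                              n_maps=n_subjects)
    maps += np.outer(fc, bump)
    return maps, thresholds, fc
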