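"""Somatosensory-evoked-field averaging, ROI scouts, and paired-pulse gating.

The paired-pulse (PP) response rides on the tail of the first pulse's
response; assuming linear superposition, subtracting the single-pulse (SP)
source map from the PP map isolates the second-pulse response.  The residual
is shifted by -100 ms so the second pulse sits at t = 0, baseline-corrected,
rectified, and compared to the SP response peak-by-peak.  A PP/SP ratio
below 1 indicates gating (inhibition of the second response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet
from .mesh import SourceSpace

#: analysis windows (ms) of the three SEF deflections
COMPONENT_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "N20m": (20.0, 26.0),
    "P35m": (27.0, 40.0),
    "P60m": (45.0, 71.0),
}

#: nominal synthetic peak latencies, inside the analysis windows
NOMINAL_LATENCIES_MS: dict[str, float] = {
    "N20m": 22.0, "P35m": 33.0, "P60m": 58.0}

SCOUT_SIZE = 10


@dataclass
class ROIScout:
    component: str
    vertices: np.ndarray  # exactly SCOUT_SIZE distinct vertices
    center: int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=int)
        if len(np.unique(self.vertices)) != SCOUT_SIZE:
            raise ValueError(f"scout must have {SCOUT_SIZE} distinct vertices")


@dataclass
class EvokedSourceWaveform:
    """Rectified ROI time series of current amplitude."""

    values: np.ndarray  # (n_samples,), >= 0
    times_ms: np.ndarray
    condition: str


@dataclass
class GatingResult:
    component: str
    sp_amplitude: float
    sp_latency_ms: float
    pp_amplitude: float
    pp_latency_ms: float

    @property
    def ratio(self) -> float:
        """PP/SP peak ratio; < 1 means the second response is suppressed."""
        if self.sp_amplitude == 0:
            return np.nan
        return self.pp_amplitude / self.sp_amplitude


def average_evoked(source_epochs: EpochSet,
                   condition: str | None = None) -> np.ndarray:
    """Arithmetic mean across epochs -> (n_vertices, n_samples)."""
    if condition is not None and source_epochs.condition != condition:
        raise ValueError(
            f"epochs are {source_epochs.condition!r}, not {condition!r}")
    if source_epochs.n_epochs < 2:
        raise ValueError("need at least 2 epochs to average")
    return source_epochs.data.mean(axis=0)


def define_roi_scout(evoked_map: np.ndarray, times_ms: np.ndarray,
                     window_ms: tuple[float, float], space: SourceSpace,
                     component: str = "") -> ROIScout:
    """Scout = activation peak plus its 9 nearest mesh neighbors.

    The center is the vertex maximizing absolute amplitude inside the
    window; neighbors are ranked by geodesic edge distance with lower vertex
    index breaking ties.  Rejects a flat map (no defined peak).
    """
    mask = (times_ms >= window_ms[0] - 1e-9) & (times_ms <= window_ms[1] + 1e-9)
    if not mask.any():
        raise ValueError("window outside epoch time axis")
    seg = np.abs(evoked_map[:, mask])
    if np.ptp(seg) == 0:
        raise ValueError("flat map: activation peak undefined")
    center = int(np.argmax(seg.max(axis=1)))
    verts = space.nearest_vertices(center, SCOUT_SIZE)
    return ROIScout(component=component, vertices=verts, center=center)


def subtract_sp_from_pp(pp_map: np.ndarray, sp_map: np.ndarray) -> np.ndarray:
    """Elementwise PP - SP; removes the first-pulse waveform under
    linear superposition."""
    pp_map = np.asarray(pp_map, dtype=float)
    sp_map = np.asarray(sp_map, dtype=float)
    if pp_map.shape != sp_map.shape:
        raise ValueError("PP and SP maps must share a shape")
    return pp_map - sp_map


def shift_rectify_baseline(subtracted_map: np.ndarray, times_ms: np.ndarray,
                           sfreq: float, shift_ms: float = 100.0,
                           baseline_ms: tuple[float, float] = (-100.0, -5.0),
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Re-reference the second pulse to t = 0, baseline-correct, rectify.

    The map is shifted left by ``shift_ms`` (second-pulse latency), the
    per-vertex mean over the baseline window is removed, and absolute values
    are taken (baseline before rectification, applied identically to both
    conditions).  Returns ``(rectified_map, new_times_ms)``; the trailing
    ``shift_ms`` of samples is dropped.
    """
    n_shift = shift_ms * sfreq / 1000.0
    if abs(n_shift - round(n_shift)) > 1e-6:
        raise ValueError("shift not representable in samples")
    n_shift = int(round(n_shift))
    if n_shift >= subtracted_map.shape[1]:
        raise ValueError("shift exceeds epoch length")
    shifted = subtracted_map[:, n_shift:]
    new_times = times_ms[: shifted.shape[1]]
    mask = (new_times >= baseline_ms[0] - 1e-9) & \
           (new_times <= baseline_ms[1] + 1e-9)
    if not mask.any():
        raise ValueError("baseline window outside shifted epoch")
    base = shifted[:, mask].mean(axis=1, keepdims=True)
    return np.abs(shifted - base), new_times


def rectify_baseline(evoked_map: np.ndarray, times_ms: np.ndarray,
                     baseline_ms: tuple[float, float] = (-100.0, -5.0),
                     ) -> np.ndarray:
    """Baseline-correct then rectify (the SP-condition counterpart)."""
    mask = (times_ms >= baseline_ms[0] - 1e-9) & \
           (times_ms <= baseline_ms[1] + 1e-9)
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    base = evoked_map[:, mask].mean(axis=1, keepdims=True)
    return np.abs(evoked_map - base)


def scout_waveform(rectified_map: np.ndarray, times_ms: np.ndarray,
                   scout: ROIScout, condition: str) -> EvokedSourceWaveform:
    """ROI time series: mean of the rectified series over scout vertices."""
    return EvokedSourceWaveform(rectified_map[scout.vertices].mean(axis=0),
                                np.asarray(times_ms, dtype=float), condition)


def peak_in_window(waveform: EvokedSourceWaveform,
                   window_ms: tuple[float, float]) -> tuple[float, float]:
    """Maximum value and its latency within a window; ties -> earliest."""
    t = waveform.times_ms
    mask = (t >= window_ms[0] - 1e-9) & (t <= window_ms[1] + 1e-9)
    if not mask.any():
        raise ValueError("empty peak window")
    idx = np.nonzero(mask)[0]
    seg = waveform.values[idx]
    k = int(np.argmax(seg))  # argmax returns the first (earliest) maximum
    return float(seg[k]), float(t[idx[k]])


def gating_ratio(pp_peak: float, sp_peak: float) -> float:
    """PP/SP amplitude ratio; NaN (flagged) when the SP peak is zero."""
    if sp_peak == 0:
        return np.nan
    if sp_peak < 0:
        raise ValueError("SP peak must be non-negative (rectified)")
    return pp_peak / sp_peak


def analyze_gating(sp_source_epochs: EpochSet, pp_source_epochs: EpochSet,
                   space: SourceSpace,
                   windows_ms: dict[str, tuple[float, float]] | None = None,
                   shift_ms: float = 100.0,
                   baseline_ms: tuple[float, float] = (-100.0, -5.0),
                   ) -> list[GatingResult]:
    """Full per-subject gating analysis on source epochs.

    Scouts are defined per condition from that condition's first-response
    map (the PP first response equals the SP response plus the overlapping
    tail, so both center on S1), then peaks are read from the rectified SP
    map and the rectified, shifted PP - SP map.
    """
    windows = windows_ms or COMPONENT_WINDOWS_MS
    times = sp_source_epochs.times_ms
    sp_map = average_evoked(sp_source_epochs)
    pp_map = average_evoked(pp_source_epochs)
    sp_rect = rectify_baseline(sp_map, times, baseline_ms)
    sub = subtract_sp_from_pp(pp_map, sp_map)
    pp_rect, pp_times = shift_rectify_baseline(
        sub, times, sp_source_epochs.sfreq, shift_ms, baseline_ms)
    results = []
    for comp, win in windows.items():
        sp_scout = define_roi_scout(sp_map, times, win, space, comp)
        pp_scout = define_roi_scout(pp_map, times, win, space, comp)
        sp_wave = scout_waveform(sp_rect, times, sp_scout, "SP")
        pp_wave = scout_waveform(pp_rect, pp_times, pp_scout, "PP")
        sp_amp, sp_lat = peak_in_window(sp_wave, win)
        pp_amp, pp_lat = peak_in_window(pp_wave, win)
        results.append(GatingResult(comp, sp_amp, sp_lat, pp_amp, pp_lat))
    return results


def gating_table(results: list[GatingResult],
                 subject: str | int = 0) -> pd.DataFrame:
    """CSV-ready table: one row per component with peaks and PP/SP ratio."""
    rows = [{"subject": subject, "component": r.component,
             "sp_amp": r.sp_amplitude, "pp_amp": r.pp_amplitude,
             "sp_lat": r.sp_latency_ms, "pp_lat": r.pp_latency_ms,
             "ratio": r.ratio} for r in results]
    return pd.DataFrame(rows)
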