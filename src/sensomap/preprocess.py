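"""Sensor-space preprocessing: filtering, segmentation, epoching, baseline
correction, and automated trial rejection.

Filtering is zero-phase: a linear-phase FIR kernel applied forward and
backward (scipy ``filtfilt``) with reflection padding.  Visual bad-trial
inspection is replaced by a deterministic peak-to-peak threshold so reruns
are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal as sig

from .containers import EpochSet, SensorRecording

logger = logging.getLogger(__name__)


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def design_bandpass(low_hz: float, high_hz: float, sfreq: float,
                    transition_hz: float | None = None) -> np.ndarray:
    """Linear-phase (type I, even order) FIR band-pass kernel."""
    nyq = sfreq / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    if transition_hz is None:
        transition_hz = max(min(low_hz / 2.0, 2.0), 0.25)
    numtaps = _odd(int(np.ceil(3.3 * sfreq / transition_hz)))
    return sig.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=sfreq)


def design_notch(notch_hz: float, sfreq: float,
                 half_width_hz: float = 2.0) -> np.ndarray:
    """Linear-phase FIR band-stop kernel centered on ``notch_hz``."""
    nyq = sfreq / 2.0
    if not 0 < notch_hz < nyq:
        raise ValueError("notch frequency must be below Nyquist")
    numtaps = _odd(int(np.ceil(6.6 * sfreq / half_width_hz)))
    return sig.firwin(numtaps,
                      [notch_hz - half_width_hz, notch_hz + half_width_hz],
                      pass_zero=True, fs=sfreq)


def _zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward application of a symmetric FIR via FFT convolution.

    Reflection ("even") padding of one kernel length on each side bounds
    edge transients; FFT convolution keeps long kernels tractable on long
    recordings (direct-form filtering would be O(n_samples * n_taps)).
    """
    p = min(len(taps), x.shape[-1] - 1)
    left = x[..., 1:p + 1][..., ::-1]
    right = x[..., -p - 1:-1][..., ::-1]
    xp = np.concatenate([left, x, right], axis=-1)
    shape = (1,) * (x.ndim - 1) + (len(taps),)
    y = sig.fftconvolve(xp, taps.reshape(shape), mode="same", axes=-1)
    y = sig.fftconvolve(y, taps[::-1].reshape(shape), mode="same", axes=-1)
    return y[..., p:p + x.shape[-1]]


def bandpass_notch(recording: SensorRecording, low_hz: float = 0.5,
                   high_hz: float = 100.0,
                   notch_hz: float | None = 50.0) -> SensorRecording:
    """Zero-phase band-pass plus optional power-line notch.

    The defaults mirror a wide-band MEG cleanup (0.5-100 Hz pass band,
    50 Hz notch).  Pass ``notch_hz=None`` to skip the notch (e.g. when the
    band-pass already excludes the line frequency).
    """
    taps = design_bandpass(low_hz, high_hz, recording.sfreq)
    out = _zero_phase(recording.data, taps)
    if notch_hz is not None:
        if notch_hz >= recording.sfreq / 2.0:
            raise ValueError("notch above Nyquist")
        out = _zero_phase(out, design_notch(notch_hz, recording.sfreq))
    return SensorRecording(out, recording.sfreq, recording.sensors)


def segment_rest(recording: SensorRecording,
                 window_ms: float = 2000.0) -> EpochSet:
    """Cut a continuous recording into consecutive non-overlapping windows.

    The trailing remainder shorter than one window is dropped.
    """
    n_win = int(round(window_ms * recording.sfreq / 1000.0))
    if recording.n_samples < n_win:
        raise ValueError("recording shorter than one segmentation window")
    n_ep = recording.n_samples // n_win
    data = recording.data[:, : n_ep * n_win]
    data = data.reshape(recording.n_channels, n_ep, n_win).transpose(1, 0, 2)
    return EpochSet(data.copy(), recording.sfreq, tmin_ms=0.0,
                    condition="rest", sensors=recording.sensors)


def epoch_evoked(recording: SensorRecording, events: pd.DataFrame,
                 tmin_ms: float = -1500.0, tmax_ms: float = 2500.0,
                 condition: str | None = None) -> EpochSet:
    """Extract trigger-locked epochs.

    ``events`` must have columns ``sample`` and ``condition``; paired-pulse
    trials are locked to the first pulse's trigger.  Events whose window
    would run past an edge are skipped with a logged warning.
    """
    if condition is not None:
        events = events[events["condition"] == condition]
    if len(events) == 0:
        raise ValueError("no events for requested condition")
    conds = events["condition"].unique()
    if len(conds) != 1:
        raise ValueError("epoch_evoked needs a single condition; pass one")
    off0 = int(round(tmin_ms * recording.sfreq / 1000.0))
    off1 = int(round(tmax_ms * recording.sfreq / 1000.0))
    n_len = off1 - off0
    chunks, skipped = [], 0
    for s in events["sample"].to_numpy():
        a, b = int(s) + off0, int(s) + off0 + n_len
        if a < 0 or b > recording.n_samples:
            skipped += 1
            continue
        chunks.append(recording.data[:, a:b])
    if skipped:
        logger.warning("epoch_evoked: skipped %d events near edges", skipped)
    if not chunks:
        raise ValueError("all events fell outside the recording")
    return EpochSet(np.stack(chunks), recording.sfreq, tmin_ms=off0 * 1000.0
                    / recording.sfreq, condition=str(conds[0]),
                    sensors=recording.sensors)


def baseline_correct(epochs: EpochSet, start_ms: float = -100.0,
                     stop_ms: float = -5.0) -> EpochSet:
    """Subtract the per-epoch, per-row mean over the baseline window."""
    sl = epochs.time_window_slice(start_ms, stop_ms)
    base = epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    return epochs.copy_with(epochs.data - base)


@dataclass
class RejectionReport:
    n_in: int
    n_rejected: int
    rejected_indices: np.ndarray

    @property
    def fraction_rejected(self) -> float:
        return self.n_rejected / self.n_in if self.n_in else 0.0


def reject_trials(epochs: EpochSet, peak_to_peak_limit: float
                  ) -> tuple[EpochSet, RejectionReport]:
    """Drop epochs whose maximum channel peak-to-peak exceeds the limit."""
    if not peak_to_peak_limit > 0:
        raise ValueError("peak_to_peak_limit must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    bad = np.nonzero(ptp.max(axis=1) > peak_to_peak_limit)[0]
    if len(bad) == epochs.n_epochs:
        raise ValueError("all trials rejected; cannot proceed")
    keep = np.setdiff1d(np.arange(epochs.n_epochs), bad)
    report = RejectionReport(epochs.n_epochs, len(bad), bad)
    if len(bad):
        logger.info("reject_trials: removed %d/%d epochs (%.1f%%)",
                    len(bad), epochs.n_epochs,
                    100 * report.fraction_rejected)
    return epochs.copy_with(epochs.data[keep]), report
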