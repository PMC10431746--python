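"""In-memory data containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sensors import SensorArray

REST = "rest"
SP = "SP"
PP = "PP"


@dataclass
class SensorRecording:
    """Continuous multichannel sensor time series.

    data : (n_channels, n_samples), sensor units.
    sfreq : sampling rate, Hz.
    sensors : channel geometry/metadata; length must match data rows.
    """

    data: np.ndarray
    sfreq: float
    sensors: SensorArray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite sensor values")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.sensors.n_channels != self.data.shape[0]:
            raise ValueError("channel metadata length != channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq


@dataclass
class SourceTimeCourses:
    """Continuous per-vertex source series, (n_vertices, n_samples)."""

    data: np.ndarray
    sfreq: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (vertices, samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]


@dataclass
class EpochSet:
    """Epoched data, sensor- or source-space.

    data : (n_epochs, n_rows, n_samples) where rows are channels or vertices.
    tmin_ms : time of the first sample relative to the trigger (evoked) or
        epoch start (rest), milliseconds.
    condition : "rest" | "SP" | "PP".
    """

    data: np.ndarray
    sfreq: float
    tmin_ms: float
    condition: str
    kind: str = "sensor"  # "sensor" | "source"
    sensors: SensorArray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, rows, samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.condition not in (REST, SP, PP):
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Strictly increasing time axis in milliseconds."""
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.sfreq

    def time_window_slice(self, start_ms: float, stop_ms: float) -> slice:
        """Samples with ``start_ms <= t <= stop_ms`` (inclusive in ms)."""
        t = self.times_ms
        idx = np.nonzero((t >= start_ms - 1e-9) & (t <= stop_ms + 1e-9))[0]
        if idx.size == 0:
            raise ValueError(f"window [{start_ms}, {stop_ms}] ms is empty")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def copy_with(self, data: np.ndarray, **kw) -> "EpochSet":
        params = dict(sfreq=self.sfreq, tmin_ms=self.tmin_ms,
                      condition=self.condition, kind=self.kind,
                      sensors=self.sensors)
        params.update(kw)
        return EpochSet(data, **params)
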