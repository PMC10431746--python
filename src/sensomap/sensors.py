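"""Sensor array geometry.

Synthetic arrays are helmet-like shells of point magnetometers measuring the
radial field component; planar gradiometers are modeled as the difference of
two point magnetometers divided by the baseline length (units T/m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAGNETOMETER = "mag"
GRADIOMETER = "grad"


@dataclass
class SensorArray:
    """Measurement geometry.

    positions : (n, 3) sensor locations, metres, head frame.
    orientations : (n, 3) unit measurement directions.
    types : (n,) array of "mag" / "grad".
    baselines : (n, 3) gradiometer baseline vectors (zero rows for
        magnetometers); a gradiometer channel reads
        ``(B(p + b/2) - B(p - b/2)) . o / |b|``.
    """

    positions: np.ndarray
    orientations: np.ndarray
    types: np.ndarray
    baselines: np.ndarray | None = None
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.types = np.asarray(self.types)
        n = len(self.positions)
        if self.baselines is None:
            self.baselines = np.zeros((n, 3))
        self.baselines = np.asarray(self.baselines, dtype=float)
        if not (len(self.orientations) == len(self.types)
                == len(self.baselines) == n):
            raise ValueError("sensor metadata lengths disagree")
        norms = np.linalg.norm(self.orientations, axis=1)
        self.orientations = self.orientations / norms[:, None]
        if not self.names:
            self.names = [f"{t.upper()}{i:03d}" for i, t in
                          enumerate(self.types)]

    @property
    def n_channels(self) -> int:
        return len(self.positions)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere points (deterministic)."""
    k = np.arange(n, dtype=float)
    ga = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    th = ga * k
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def make_helmet_array(n_sensors: int = 64, radius: float = 0.12,
                      z_min_frac: float = -0.45) -> SensorArray:
    """Helmet shell of radial magnetometers.

    Points are drawn from a Fibonacci lattice and kept where
    ``z > z_min_frac * radius`` (a whole-head helmet leaves the neck open);
    ``n_sensors`` is the retained channel count.
    """
    # oversample so that the retained upper-shell count is n_sensors
    frac = (1.0 - z_min_frac) / 2.0
    n_total = int(np.ceil(n_sensors / frac)) + 8
    pts = _fibonacci_sphere(n_total)
    keep = pts[:, 2] > z_min_frac
    pts = pts[keep][:n_sensors]
    if len(pts) < n_sensors:
        raise ValueError("could not place requested sensor count")
    positions = pts * radius
    orientations = pts.copy()  # radial
    types = np.array([MAGNETOMETER] * n_sensors)
    return SensorArray(positions, orientations, types)


def make_gradiometer_array(n_sensors: int = 64, radius: float = 0.12,
                           baseline: float = 0.017) -> SensorArray:
    """Planar-gradiometer variant of the helmet array."""
    mags = make_helmet_array(n_sensors=n_sensors, radius=radius)
    # tangential baseline direction: project global x onto the tangent plane
    rad = mags.orientations
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (n_sensors, 1))
    near_pole = np.abs(rad @ np.array([1.0, 0.0, 0.0])) > 0.9
    ref[near_pole] = [0.0, 1.0, 0.0]
    tang = ref - (np.sum(ref * rad, axis=1, keepdims=True)) * rad
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    types = np.array([GRADIOMETER] * n_sensors)
    return SensorArray(mags.positions, rad, types, baselines=tang * baseline)
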