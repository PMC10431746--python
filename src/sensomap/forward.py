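"""Spherical-conductor MEG forward solution.

The magnetic field of a current dipole inside a homogeneous spherical
conductor has a closed form (Sarvas): it depends only on the sphere center,
not on the radius or conductivity, and a purely radial dipole produces no
external field.  Gradiometer channels are modeled as differenced point
magnetometers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import SourceSpace
from .sensors import GRADIOMETER, SensorArray

MU0_OVER_4PI = 1e-7  # T m / (A m)


@dataclass
class LeadField:
    """Forward operator.

    free : (n_channels, n_vertices, 3) field per unit dipole moment along
        x/y/z, T per A.m (T/m per A.m for gradiometer rows).
    constrained : (n_channels, n_vertices) after projection onto the
        outward surface normals, or None.
    """

    free: np.ndarray
    constrained: np.ndarray | None = None
    sphere_center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.free = np.asarray(self.free, dtype=float)
        if self.free.ndim != 3 or self.free.shape[2] != 3:
            raise ValueError("free lead field must be (channels, vertices, 3)")
        if not np.isfinite(self.free).all():
            raise ValueError("non-finite lead field")

    @property
    def n_channels(self) -> int:
        return self.free.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.free.shape[1]

    def constrain(self, normals: np.ndarray) -> np.ndarray:
        """Project onto per-vertex orientations -> (channels, vertices)."""
        self.constrained = np.einsum("cvk,vk->cv", self.free, normals)
        return self.constrained


def dipole_field(r_dip: np.ndarray, q: np.ndarray, r_sens: np.ndarray,
                 center: np.ndarray | None = None) -> np.ndarray:
    """Magnetic field B of a current dipole in a spherical conductor.

    Parameters
    ----------
    r_dip : (3,) dipole position, m.
    q : (3,) dipole moment, A.m.
    r_sens : (n, 3) field points outside the conductor, m.
    center : (3,) sphere center, default origin.

    Returns
    -------
    (n, 3) field vectors in tesla (Sarvas closed form).
    """
    r_dip = np.asarray(r_dip, dtype=float)
    q = np.asarray(q, dtype=float)
    r_sens = np.atleast_2d(np.asarray(r_sens, dtype=float))
    if center is not None:
        r_dip = r_dip - center
        r_sens = r_sens - center

    r0n = np.linalg.norm(r_dip)
    rn = np.linalg.norm(r_sens, axis=1)
    if np.any(rn <= r0n):
        raise ValueError("field points must lie outside the source radius")

    a_vec = r_sens - r_dip
    a = np.linalg.norm(a_vec, axis=1)
    if np.any(a == 0) or r0n == 0 and np.allclose(q, 0):
        raise ValueError("degenerate geometry")

    ar = np.einsum("ij,j->i", r_sens, r_dip)  # r . r0
    av_r = np.einsum("ij,ij->i", a_vec, r_sens)  # a . r
    F = a * (rn * a + rn**2 - ar)
    gF = ((a**2 / rn + av_r / a + 2 * a + 2 * rn)[:, None] * r_sens
          - (a + 2 * rn + av_r / a)[:, None] * r_dip)
    qxr0 = np.cross(q, r_dip)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * qxr0[None, :]
        - (np.einsum("j,ij->i", qxr0, r_sens))[:, None] * gF)
    return B


def _channel_response(sensors: SensorArray, B_at) -> np.ndarray:
    """Evaluate each channel's reading given a field functional.

    ``B_at(points)`` returns (n_points, 3) field vectors.
    """
    out = np.empty(sensors.n_channels)
    is_grad = sensors.types == GRADIOMETER
    if np.any(~is_grad):
        idx = np.nonzero(~is_grad)[0]
        B = B_at(sensors.positions[idx])
        out[idx] = np.einsum("ij,ij->i", B, sensors.orientations[idx])
    if np.any(is_grad):
        idx = np.nonzero(is_grad)[0]
        b = sensors.baselines[idx]
        blen = np.linalg.norm(b, axis=1)
        Bp = B_at(sensors.positions[idx] + b / 2)
        Bm = B_at(sensors.positions[idx] - b / 2)
        out[idx] = np.einsum("ij,ij->i", Bp - Bm,
                             sensors.orientations[idx]) / blen
    return out


def sphere_forward(source_space: SourceSpace, sensors: SensorArray,
                   sphere_center: np.ndarray | tuple = (0.0, 0.0, 0.0),
                   constrain: bool = True,
                   normalize: bool = False) -> LeadField:
    """Lead field of every source vertex under the spherical model.

    Sources must lie strictly inside the sensor shell (and off the sphere
    center, where the model is degenerate).  With ``normalize=True`` the
    whole operator is rescaled so the median constrained-column norm is 1,
    which gives simulations a sensor-unit scale of order one; the rescaling
    is a single global factor, so unit gain and linearity are untouched.
    """
    center = np.asarray(sphere_center, dtype=float)
    verts = source_space.vertices - center
    sens_r = np.linalg.norm(sensors.positions - center, axis=1)
    src_r = np.linalg.norm(verts, axis=1)
    if np.any(src_r == 0):
        raise ValueError("source at sphere center")
    if np.any(src_r >= sens_r.min()):
        raise ValueError("sources must lie strictly inside the sensor shell")

    n_ch = sensors.n_channels
    n_v = source_space.n_vertices
    free = np.empty((n_ch, n_v, 3))
    eye = np.eye(3)
    for v in range(n_v):
        rv = source_space.vertices[v]
        for k in range(3):
            free[:, v, k] = _channel_response(
                sensors, lambda pts: dipole_field(rv, eye[k], pts,
                                                  center=center))
    lf = LeadField(free, sphere_center=center)
    lf.constrain(source_space.normals)
    if normalize:
        scale = np.median(np.linalg.norm(lf.constrained, axis=0))
        if scale > 0:
            lf.free /= scale
            lf.constrained /= scale
    return lf
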