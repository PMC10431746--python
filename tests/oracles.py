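"""Independent numerical oracles used by the test suite.

These implementations deliberately avoid the package's computational paths:
the forward-field reference integrates the conductor's volume currents
numerically (in their exact boundary form) from a spherical-harmonic
solution of the potential; the rank-test references enumerate permutations
and sign patterns exhaustively; the TFCE reference loops over thresholds
with an off-the-shelf connected-component routine.
"""

from __future__ import annotations

import itertools


import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

MU0_OVER_4PI = 1e-7


# ---------------------------------------------------------------------------
# forward model reference


def _legendre_sum(t: np.ndarray, cosg: np.ndarray, lmax: int) -> np.ndarray:
    """sum_{l>=1} ((l+1)/l) t^l P_l(cos gamma), vectorized recurrence."""
    p_prev = np.ones_like(cosg)   # P_0
    p_cur = cosg.copy()           # P_1
    tl = t.copy()
    out = 2.0 * tl * p_cur
    for ell in range(2, lmax + 1):
        p_next = ((2 * ell - 1) * cosg * p_cur
                  - (ell - 1) * p_prev) / ell
        tl = tl * t
        out += ((ell + 1) / ell) * tl * p_next
        p_prev, p_cur = p_cur, p_next
    return out


def sphere_potential(points: np.ndarray, source_pos: np.ndarray,
                     currents: float, R: float, lmax: int = 90,
                     sigma: float = 1.0) -> np.ndarray:
    """Electric potential of point current sources inside an insulated
    conducting sphere (center at origin).

    ``source_pos`` is (k, 3), ``currents`` (k,) summing to ~0.  The
    boundary-corrected series is
    ``V = I/(4 pi sigma) [1/d + sum_l ((l+1)/l) (b rho / R^2)^l P_l / R]``.
    """
    points = np.atleast_2d(points)
    V = np.zeros(len(points))
    rho = np.linalg.norm(points, axis=1)
    for pos, cur in zip(np.atleast_2d(source_pos), np.atleast_1d(currents)):
        b = np.linalg.norm(pos)
        d = np.linalg.norm(points - pos, axis=1)
        with np.errstate(divide="ignore"):
            direct = 1.0 / d
        if b == 0:
            series = np.zeros_like(rho)
        else:
            cosg = (points @ pos) / np.where(rho * b == 0, 1.0, rho * b)
            cosg = np.clip(cosg, -1.0, 1.0)
            t = b * rho / R ** 2
            series = _legendre_sum(t, cosg, lmax) / R
        V += cur / (4 * np.pi * sigma) * (direct + series)
    return V


def quadrature_sphere_field(r_dip: np.ndarray, q: np.ndarray,
                            r_sens: np.ndarray, R: float,
                            n_theta: int = 160, n_phi: int = 320,
                            lmax: int = 90,
                            delta_frac: float = 5e-4) -> np.ndarray:
    """Magnetic field of a current dipole in a homogeneous conducting
    sphere, by numeric quadrature of the volume-current contribution.

    The Biot-Savart integral of the return currents over the conductor is
    taken in its exact boundary form (divergence theorem): the volume
    currents of a homogeneous region are magnetically equivalent to the
    surface distribution ``sigma V n``, so

    ``B = B_primary + mu0/(4 pi) * sigma * oint V(r') (r - r')
          / |r - r'|^3 x n' dS'``

    with the surface potential from the spherical-harmonic series and the
    dipole realized as a close monopole pair.  Everything here is
    independent of the closed-form solution under test.
    """
    r_dip = np.asarray(r_dip, dtype=float)
    q = np.asarray(q, dtype=float)
    r_sens = np.atleast_2d(np.asarray(r_sens, dtype=float))
    qn = np.linalg.norm(q)
    if qn == 0:
        return np.zeros_like(r_sens)
    delta = delta_frac * R
    qhat = q / qn
    sources = np.array([r_dip + qhat * delta / 2,
                        r_dip - qhat * delta / 2])
    currents = np.array([qn / delta, -qn / delta])

    # Gauss-Legendre x trapezoid surface grid
    x, wx = np.polynomial.legendre.leggauss(n_theta)
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    w_phi = 2 * np.pi / n_phi
    ct, ph = np.meshgrid(x, phi, indexing="ij")
    st = np.sqrt(1 - ct ** 2)
    normals = np.stack([st * np.cos(ph), st * np.sin(ph), ct],
                       axis=-1).reshape(-1, 3)
    weights = (np.outer(wx, np.full(n_phi, w_phi)) * R ** 2).ravel()
    surf = normals * R

    V = sphere_potential(surf, sources, currents, R, lmax=lmax)

    out = np.empty_like(r_sens)
    for i, rs in enumerate(r_sens):
        diff = rs - surf
        kern = diff / np.linalg.norm(diff, axis=1)[:, None] ** 3
        integrand = np.cross(kern, normals)
        B_surf = MU0_OVER_4PI * np.einsum(
            "j,jk->k", weights * V, integrand)
        a = rs - r_dip
        B_prim = MU0_OVER_4PI * np.cross(q, a) / np.linalg.norm(a) ** 3
        out[i] = B_prim + B_surf
    return out


# ---------------------------------------------------------------------------
# exact rank-test references


def spearman_exact_enum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-tailed exact Spearman p by looping over all n! orderings."""
    rx = rankdata(x)
    ry = rankdata(y)
    r_obs = np.corrcoef(rx, ry)[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return float(r_obs), count / total


def wilcoxon_exact_enum(d: np.ndarray) -> tuple[float, float]:
    """Two-tailed exact signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(ranks[np.array(signs, dtype=bool)].sum())
    w_all = np.array(w_all)
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return float(w_obs), float(min(1.0, 2 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# TFCE reference


def tfce_reference(values: np.ndarray, adjacency: sp.spmatrix, E: float,
                   H: float, n_steps: int) -> np.ndarray:
    """Per-threshold loop with scipy connected components (one-sided,
    non-negative input), the textbook TFCE discretization."""
    values = np.asarray(values, dtype=float)
    vmax = values.max()
    out = np.zeros_like(values)
    if vmax <= 0:
        return out
    dh = vmax / n_steps
    adj = adjacency.tocsr()
    for k in range(1, n_steps + 1):
        h = k * dh
        mask = values >= h
        if not mask.any():
            break
        idx = np.nonzero(mask)[0]
        sub = adj[idx][:, idx]
        _, labels = connected_components(sub, directed=False)
        sizes = np.bincount(labels)
        out[idx] += (sizes[labels] ** E) * (h ** H) * dh
    return out


# ---------------------------------------------------------------------------
# psychometric likelihood grid


def psychometric_grid_mle(distances: np.ndarray, responses: np.ndarray,
                          thr_grid: np.ndarray,
                          slope_grid: np.ndarray) -> tuple[float, float]:
    """Brute-force maximum of the Bernoulli log-likelihood over a
    (threshold, slope) grid."""
    best = (-np.inf, np.nan, np.nan)
    for thr in thr_grid:
        eta = np.outer(slope_grid, distances - thr)
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = (responses * np.log(p)
              + (1 - responses) * np.log(1 - p)).sum(axis=1)
        k = int(np.argmax(ll))
        if ll[k] > best[0]:
            best = (ll[k], thr, slope_grid[k])
    return best[1], best[2]
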