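"""Group-level statistics: vertex-wise brain-behavior regression with
TFCE permutation family-wise-error control, plus rank-based tests.

TFCE (threshold-free cluster enhancement) integrates, over supra-threshold
heights h, the extent of the connected component containing each vertex:
``TFCE(v) = sum_h e(v, h)^E * h^H * dh``.  The family-wise null is the
distribution of the map maximum of |TFCE| under permutations of the
behavioral covariate across subjects (single-regressor exchangeability).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from numba import njit
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

_T_CAP = 1e6          # stand-in for |t| at numerically perfect fits
_EXACT_SPEARMAN_N = 9  # enumerate n! rank permutations up to here


@dataclass
class TFCEParams:
    E: float = 0.5
    H: float = 2.0
    n_permutations: int = 1000
    n_steps: int = 100          # used when dh is None: dh = map max / n_steps
    dh: float | None = None     # explicit threshold step (fixed grid)
    k_min: int = 50             # cluster extent floor
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")


@dataclass
class VertexStatMap:
    t: np.ndarray
    tfce: np.ndarray | None = None
    p_fwe: np.ndarray | None = None
    flagged: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_vertices(self) -> int:
        return len(self.t)


def vertexwise_regression(maps: np.ndarray,
                          covariate: np.ndarray) -> VertexStatMap:
    """Two-tailed OLS slope t-statistic of map value on covariate, per vertex.

    Zero-variance vertices get t = 0 and are flagged; numerically perfect
    fits (|r| -> 1) are capped at +-1e6 and flagged.
    """
    maps = np.asarray(maps, dtype=float)
    x = np.asarray(covariate, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 subjects")
    if x.std() == 0:
        raise ValueError("covariate has zero variance")
    t, flagged = _t_maps(maps[:, None, :], x[None, :])
    return VertexStatMap(t[0], flagged=flagged)


def _t_maps(maps: np.ndarray, xs: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized slope t-statistics.

    maps : (n_subjects, 1, V) broadcast against xs (B, n_subjects) ->
    (B, V).  Returns (t, flagged_vertex_indices).
    """
    y = maps[:, 0, :]                      # (S, V)
    S = y.shape[0]
    yc = y - y.mean(axis=0, keepdims=True)
    ystd = np.sqrt((yc ** 2).sum(axis=0))
    xc = xs - xs.mean(axis=1, keepdims=True)
    xstd = np.sqrt((xc ** 2).sum(axis=1))
    num = xc @ yc                           # (B, V)
    denom = np.outer(xstd, ystd)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    one_minus = 1.0 - r ** 2
    t = np.empty_like(r)
    good = one_minus > 1.0 / _T_CAP ** 2
    t[good] = r[good] * np.sqrt((S - 2) / one_minus[good])
    t[~good] = np.sign(r[~good]) * _T_CAP
    zero_var = np.nonzero(ystd == 0)[0]
    t[:, zero_var] = 0.0
    perfect = np.nonzero((~good).any(axis=0))[0]
    flagged = np.union1d(zero_var, perfect)
    return t, flagged


@njit(cache=True)
def _uf_find(parent, v):
    while parent[v] != v:
        parent[v] = parent[parent[v]]
        v = parent[v]
    return v


@njit(cache=True)
def _tfce_one_sided(values, indptr, indices, E, H, dh, n_steps):
    """Union-find TFCE of a non-negative map, thresholds descending."""
    n = values.shape[0]
    order = np.argsort(-values)
    parent = np.empty(n, dtype=np.int64)
    size = np.ones(n, dtype=np.int64)
    active = np.zeros(n, dtype=np.uint8)
    score = np.zeros(n)
    p = 0
    for k in range(n_steps, 0, -1):
        h = k * dh
        while p < n and values[order[p]] >= h:
            v = order[p]
            parent[v] = v
            active[v] = 1
            for jj in range(indptr[v], indptr[v + 1]):
                u = indices[jj]
                if active[u]:
                    ru = _uf_find(parent, u)
                    rv = _uf_find(parent, v)
                    if ru != rv:
                        if size[ru] < size[rv]:
                            ru, rv = rv, ru
                        parent[rv] = ru
                        size[ru] += size[rv]
            p += 1
        inc = (h ** H) * dh
        for i in range(p):
            v = order[i]
            score[v] += (size[_uf_find(parent, v)] ** E) * inc
    return score


def tfce_enhance(stat_map: np.ndarray, adjacency: sp.spmatrix,
                 params: TFCEParams | None = None) -> np.ndarray:
    """Two-tailed TFCE: positive and negative parts enhanced separately.

    Returns a signed map: the negative tail is enhanced on ``-map`` and
    subtracted.  Per sign, ``dh = max / n_steps`` by default so the
    integration grid always spans the observed range; an explicit
    ``params.dh`` fixes the grid instead (under a common fixed grid the
    enhancement is exactly monotone in the input map).
    """
    params = params or TFCEParams()
    values = np.asarray(stat_map, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("stat map must be finite")
    adj = adjacency.tocsr()
    indptr = adj.indptr.astype(np.int64)
    indices = adj.indices.astype(np.int64)
    out = np.zeros_like(values)
    for sign in (1.0, -1.0):
        v = np.clip(sign * values, 0.0, None)
        vmax = v.max()
        if vmax <= 0:
            continue
        if params.dh is None:
            dh, n_steps = vmax / params.n_steps, params.n_steps
        else:
            dh = params.dh
            n_steps = int(np.ceil(vmax / dh - 1e-12))
        out += sign * _tfce_one_sided(v, indptr, indices, params.E,
                                      params.H, dh, n_steps)
    return out


def permutation_fwe(maps: np.ndarray, covariate: np.ndarray,
                    adjacency: sp.spmatrix,
                    params: TFCEParams | None = None,
                    rng_seed: int | None = 0) -> VertexStatMap:
    """Max-statistic TFCE permutation test with FWE-corrected p-values.

    The covariate is shuffled across subjects; each permutation regenerates
    the full t -> TFCE map, and the null is the permutation distribution of
    the map maximum of |TFCE|.  Sampled permutations use the add-one
    estimator ``p = (1 + #{max_b >= |T(v)|}) / (1 + B)``; when ``B`` exceeds
    ``n!`` the permutation group is enumerated exactly instead.
    """
    params = params or TFCEParams()
    maps = np.asarray(maps, dtype=float)
    x = np.asarray(covariate, dtype=float)
    n = len(x)
    obs = vertexwise_regression(maps, x)
    obs_tfce = tfce_enhance(obs.t, adjacency, params)

    n_fact = math.factorial(n)
    exact = params.n_permutations >= n_fact
    if exact:
        perms = np.array(list(itertools.permutations(range(n))))
        xs = x[perms]
    else:
        rng = np.random.default_rng(rng_seed)
        xs = np.stack([rng.permutation(x)
                       for _ in range(params.n_permutations)])
    t_perm, _ = _t_maps(maps[:, None, :], xs)
    null_max = np.empty(len(xs))
    for b in range(len(xs)):
        null_max[b] = np.abs(
            tfce_enhance(t_perm[b], adjacency, params)).max()
    a = np.abs(obs_tfce)
    counts = (null_max[None, :] >= a[:, None] - 1e-12).sum(axis=1)
    if exact:
        p = counts / n_fact
    else:
        p = (1.0 + counts) / (1.0 + len(xs))
    return VertexStatMap(obs.t, tfce=obs_tfce, p_fwe=p,
                         flagged=obs.flagged)


def cluster_filter(p_map: np.ndarray, adjacency: sp.spmatrix,
                   alpha: float = 0.05, k_min: int = 50) -> pd.DataFrame:
    """Connected components of significant vertices, small ones dropped.

    Components need extent k_E > ``k_min`` to be reported.  The table lists
    cluster id, extent, peak vertex (smallest p, lower index on ties) and
    peak p.
    """
    p_map = np.asarray(p_map, dtype=float)
    mask = p_map < alpha
    rows = []
    if mask.any():
        idx = np.nonzero(mask)[0]
        sub = adjacency.tocsr()[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            if len(members) <= k_min:
                continue
            peak = members[np.argmin(p_map[members])]
            rows.append({"cluster": len(rows) + 1, "k_e": len(members),
                         "peak_vertex": int(peak),
                         "peak_p": float(p_map[peak])})
    df = pd.DataFrame(rows, columns=["cluster", "k_e", "peak_vertex",
                                     "peak_p"])
    return df.sort_values("k_e", ascending=False,
                          ignore_index=True) if len(df) else df


@dataclass
class RankTestResult:
    statistic: float
    p: float
    p_bonferroni: float
    n: int
    flagged: bool = False
    method: str = ""


def _rankdata(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, method="average")


def spearman(x: np.ndarray, y: np.ndarray,
             n_comparisons: int = 1) -> RankTestResult:
    """Two-tailed Spearman rank correlation with Bonferroni adjustment.

    For n <= 9 the p-value is exact: the permutation distribution of the
    rank correlation over all n! orderings (average ranks, so ties are
    handled).  Larger samples use the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        return RankTestResult(np.nan, np.nan, np.nan, n, flagged=True,
                              method="degenerate")
    rx, ry = _rankdata(x), _rankdata(y)
    r_obs = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_SPEARMAN_N:
        perms = np.array(list(itertools.permutations(range(n))))
        ryp = ry[perms]                       # (n!, n)
        rxc = rx - rx.mean()
        ryc = ryp - ryp.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum(axis=1))
        r_perm = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(r_perm) >= abs(r_obs) - 1e-12))
        method = "exact_permutation"
    else:
        p = float(scipy.stats.spearmanr(x, y).pvalue)
        method = "t_approximation"
    return RankTestResult(r_obs, p, min(1.0, p * n_comparisons), n,
                          method=method)


def _wilcoxon_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-tailed p for the signed-rank sum via rank-polynomial DP.

    Average ranks are doubled to integers, so tied ranks are exact too.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = r2.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:len(counts) - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray,
                         n_comparisons: int = 1,
                         exact_limit: int = 25) -> RankTestResult:
    """Two-tailed Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (all-zero -> p = 1, flagged).  The null is
    exact (full sign-flip distribution) up to ``exact_limit`` pairs; beyond
    that the normal approximation with continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must share a shape")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return RankTestResult(0.0, 1.0, 1.0, 0, flagged=True,
                              method="all_zero_differences")
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = _rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        p = _wilcoxon_exact_p(w_plus, ranks)
        method = "exact"
    else:
        p = float(scipy.stats.wilcoxon(
            d, alternative="two-sided", method="approx",
            correction=True).pvalue)
        method = "normal_approximation"
    return RankTestResult(w_plus, p, min(1.0, p * n_comparisons), n,
                          method=method)
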