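"""Psychometric-function fitting for two-point discrimination.

A binomial logistic regression of the per-trial "two points" response on pin
distance gives ``P(two | d) = logistic(intercept + slope * d)``; the 50%
point, ``-intercept / slope``, is the discrimination threshold.  "Uncertain"
responses are pooled with one-point by the task's button mapping, and the
single-pin (0 mm) trials enter as distance 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import TWO_POINT

logger = logging.getLogger(__name__)

#: |slope| beyond which a fit is treated as separated and clamped (1/mm)
SLOPE_CLAMP = 50.0


@dataclass
class PsychometricFit:
    intercept: float
    slope: float                    # 1/mm
    converged: bool
    n_trials: int
    proportions: pd.DataFrame       # distance_mm, n, p_two

    @property
    def threshold_mm(self) -> float:
        """Distance at which the fitted curve crosses 0.5."""
        if self.slope <= 0:
            return np.nan
        return -self.intercept / self.slope

    def predict(self, distances_mm: np.ndarray) -> np.ndarray:
        eta = self.intercept + self.slope * np.asarray(distances_mm,
                                                       dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_psychometric(table: pd.DataFrame) -> PsychometricFit:
    """Maximum-likelihood logistic fit of P(two_point | distance).

    ``table`` needs columns ``distance_mm`` and ``response``.  The fit is
    trial-level (identical to proportion-weighted at the MLE).  Perfect
    separation is caught and returned as a non-converged fit with the slope
    clamped at ``SLOPE_CLAMP``, keeping small per-subject designs usable.
    """
    d = table["distance_mm"].to_numpy(dtype=float)
    y = (table["response"] == TWO_POINT).to_numpy(dtype=float)
    if len(np.unique(d)) < 2:
        raise ValueError("need at least 2 distinct distances")
    if y.min() == y.max():
        # all one response class: separation path
        return _separated_fit(d, y, table)
    X = sm.add_constant(d)
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=200)
        intercept, slope = float(res.params[0]), float(res.params[1])
        converged = bool(res.converged) and abs(slope) < SLOPE_CLAMP
    except Exception:  # PerfectSeparation and numerical failures
        converged = False
        intercept, slope = np.nan, np.nan
    if not converged and not np.isfinite(slope):
        return _separated_fit(d, y, table)
    if not converged:
        logger.warning("psychometric fit flagged non-converged "
                       "(slope %.2f clamped)", slope)
        slope = float(np.clip(slope, -SLOPE_CLAMP, SLOPE_CLAMP))
    return PsychometricFit(intercept, slope, converged, len(y),
                           _proportions(table))


def _separated_fit(d: np.ndarray, y: np.ndarray,
                   table: pd.DataFrame) -> PsychometricFit:
    """Clamped-slope fallback when the likelihood has no interior maximum."""
    slope = SLOPE_CLAMP
    if y.min() == y.max():
        # place the (undefined) threshold beyond the sampled range
        thr = d.max() + 1.0 if y.max() == 0 else d.min() - 1.0
    else:
        hi = d[y == 1].min()
        lo = d[y == 0].max()
        thr = 0.5 * (hi + lo)
    logger.warning("psychometric fit separated; slope clamped at %g", slope)
    return PsychometricFit(-slope * thr, slope, False, len(y),
                           _proportions(table))


def _proportions(table: pd.DataFrame) -> pd.DataFrame:
    g = table.assign(two=(table["response"] == TWO_POINT).astype(float))
    out = g.groupby("distance_mm", as_index=False).agg(
        n=("two", "size"), p_two=("two", "mean"))
    return out


def threshold_50(fit: PsychometricFit) -> float:
    """The 50% ("TPD") threshold in mm; requires a positive slope."""
    if fit.slope <= 0 or not np.isfinite(fit.slope):
        raise ValueError("threshold undefined for non-positive slope")
    return -fit.intercept / fit.slope


def fit_cohort(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per-subject fits -> table of thresholds, slopes, convergence flags."""
    rows = []
    for subject, tab in behavior.groupby("subject"):
        fit = fit_psychometric(tab)
        rows.append({"subject": subject, "threshold_mm": fit.threshold_mm,
                     "slope": fit.slope, "intercept": fit.intercept,
                     "converged": fit.converged, "n_trials": fit.n_trials})
    return pd.DataFrame(rows)
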