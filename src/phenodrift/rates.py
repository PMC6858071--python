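"""Exponential growth/death rates from CFU time series.

Growth and death of exponential-phase cultures are quantified by ordinary
least squares of log2(CFU/mL) against time; the slope times ln 2 is the
specific rate in h⁻¹ (so a 3.5-hour doubling time gives r ≈ 0.198 h⁻¹).
The phenotype-independent death coefficient α (h⁻¹·mM⁻¹) comes from
time-kill curves: the death rate at each formaldehyde concentration is
regressed against concentration, and α is the slope of that second
regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RateEstimate", "exponential_rate", "alpha_from_timekill"]


@dataclass(frozen=True)
class RateEstimate:
    """A specific rate (h⁻¹, natural-log scale) with its 95% CI half-width."""

    rate: float
    ci95: float
    r_squared: float
    n: int


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, its 95% CI half-width, and R² of a simple OLS regression."""
    res = stats.linregress(x, y)
    dof = x.size - 2
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
    return res.slope, tcrit * res.stderr, res.rvalue**2


def exponential_rate(times, cfu, window: tuple[float, float] | None = None) -> RateEstimate:
    """Specific growth (or, if negative, death) rate from a CFU time series.

    Fits log2(CFU/mL) against time over ``window`` (inclusive time range, in
    hours; default all points) and converts the slope to the natural-log
    scale.  Zero CFU observations are undefined on the log scale and are
    dropped with a warning; at least three positive points are required.
    """
    times = np.asarray(times, dtype=float)
    cfu = np.asarray(cfu, dtype=float)
    if times.shape != cfu.shape or times.ndim != 1:
        raise ValueError("times and cfu must be 1-D arrays of equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    mask = np.ones_like(times, dtype=bool)
    if window is not None:
        lo, hi = window
        mask &= (times >= lo) & (times <= hi)
    zeros = mask & (cfu <= 0)
    if zeros.any():
        warnings.warn(
            f"excluding {int(zeros.sum())} zero-CFU point(s) from log-scale regression",
            stacklevel=2,
        )
        mask &= cfu > 0
    if mask.sum() < 3:
        raise ValueError("need at least three positive CFU observations in the window")
    t, y = times[mask], np.log2(cfu[mask])
    slope, ci, r2 = _ols_slope(t, y)
    ln2 = np.log(2.0)
    return RateEstimate(rate=slope * ln2, ci95=ci * ln2, r_squared=r2, n=int(mask.sum()))


def alpha_from_timekill(
    curves: dict[float, tuple[np.ndarray, np.ndarray]],
    window: tuple[float, float] | None = None,
) -> RateEstimate:
    """Death coefficient α from time-kill curves at several concentrations.

    ``curves`` maps formaldehyde concentration (mM) to a ``(times, cfu)``
    pair.  Each curve's specific rate is estimated by
    :func:`exponential_rate`; the death rate is its negative.  α is then
    the OLS slope of death rate against concentration.  A curve that shows
    net growth enters as a negative death rate with a warning.
    """
    if len(curves) < 2:
        raise ValueError("need kill curves at ≥2 concentrations to regress a slope")
    concs, death = [], []
    for conc in sorted(curves):
        times, cfu = curves[conc]
        est = exponential_rate(times, cfu, window=window)
        if est.rate > 0:
            warnings.warn(
                f"net growth at {conc} mM; included as negative death rate", stacklevel=2
            )
        concs.append(conc)
        death.append(-est.rate)
    concs = np.asarray(concs)
    death = np.asarray(death)
    if concs.size == 2:
        slope = float(np.diff(death)[0] / np.diff(concs)[0])
        return RateEstimate(rate=slope, ci95=np.inf, r_squared=1.0, n=2)
    slope, ci, r2 = _ols_slope(concs, death)
    return RateEstimate(rate=slope, ci95=ci, r_squared=r2, n=concs.size)
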