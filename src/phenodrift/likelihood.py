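"""Log-likelihood of model-predicted vs observed CFU counts.

Plating counts span many orders of magnitude and include zeros, so both
observed and predicted cumulative CFU/mL are transformed with the inverse
hyperbolic sine, asinh(x) = ln(x + sqrt(1 + x²)), which is logarithmic for
large counts but defined (and zero) at zero.  The fit criterion is the
Gaussian log-likelihood of an ordinary linear model on that scale: by
default a regression of asinh(observed) on asinh(predicted) with free
intercept and slope (and MLE residual variance); alternatively, residuals
about the identity line (mode="identity").
"""

from __future__ import annotations

import numpy as np

__all__ = ["asinh_transform", "log_likelihood", "pseudo_r2"]

#: Floor on the MLE residual variance; a perfect fit would otherwise send
#: the Gaussian log-likelihood to +infinity.
VARIANCE_FLOOR = 1e-12


def asinh_transform(x):
    """Inverse hyperbolic sine, ln(x + sqrt(1 + x²)); asinh(0) = 0."""
    return np.arcsinh(x)


def _residuals(observed, predicted, mode: str):
    y = np.arcsinh(np.asarray(observed, dtype=float))
    x = np.arcsinh(np.asarray(predicted, dtype=float))
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be 1-D arrays of equal length")
    if y.size < 3:
        raise ValueError("need at least three (observed, predicted) pairs")
    if mode == "regression":
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    elif mode == "identity":
        resid = y - x
    else:
        raise ValueError(f"unknown likelihood mode {mode!r}")
    return y, resid


def log_likelihood(observed, predicted, mode: str = "regression") -> float:
    """Gaussian log-likelihood of the asinh-scale linear model.

    Higher is better.  The residual variance is the maximum-likelihood
    (1/n) estimate, floored at ``VARIANCE_FLOOR`` so that a numerically
    perfect fit returns a large finite value instead of +inf.
    """
    y, resid = _residuals(observed, predicted, mode)
    n = y.size
    s2 = max(float(np.mean(resid**2)), VARIANCE_FLOOR)
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def pseudo_r2(observed, predicted, mode: str = "regression") -> float:
    """Coefficient of determination of the asinh-scale linear model."""
    y, resid = _residuals(observed, predicted, mode)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant; R² undefined")
    return 1.0 - float(np.sum(resid**2)) / ss_tot
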