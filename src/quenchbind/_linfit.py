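"""Shared ordinary-least-squares helper.

All regressions in the package are unweighted OLS on a straight line,
reported with r^2 = 1 - SS_res / SS_tot.  When the response is constant
(SS_tot == 0) a perfect fit reports r^2 = 1 and anything else 0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ols_line", "r_squared"]


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def ols_line(
    x: np.ndarray, y: np.ndarray, *, through_origin: bool = False
) -> tuple[float, float, float]:
    """Fit y = slope*x + intercept by OLS.

    Returns (slope, intercept, r_squared).  With ``through_origin`` the
    intercept is fixed at 0 and the slope is sum(xy)/sum(x^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if through_origin:
        sxx = float(np.dot(x, x))
        if sxx == 0.0:
            raise ValueError("degenerate x: all zeros")
        slope = float(np.dot(x, y)) / sxx
        intercept = 0.0
    else:
        if np.ptp(x) == 0.0:
            raise ValueError("degenerate x: no spread")
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    return slope, intercept, r_squared(y, slope * x + intercept)
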