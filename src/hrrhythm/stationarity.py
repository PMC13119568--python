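"""Stationarity testing and differencing for heart-rate windows.

Raw heart-rate windows are typically non-stationary (slow drifts in
level), which biases correlogram-based features. Each window is checked
with the Augmented Dickey-Fuller (ADF) unit-root test and, following the
analysis protocol, first-order differencing is applied to *all* windows
uniformly; the ADF outcome is recorded for reporting but does not gate
the transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import adfuller

__all__ = ["ADFResult", "adf_test", "difference", "schwert_max_lag"]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class ADFResult:
    """ADF test outcome for one window.

    ``stationary`` is the decision at the 0.05 level (reject the unit
    root); ``degenerate`` marks constant windows where the regression is
    impossible, in which case statistic and p-value are NaN.
    """

    statistic: float
    p_value: float
    lags_used: int
    stationary: bool
    degenerate: bool = False


def schwert_max_lag(n: int) -> int:
    """Schwert's rule for the maximum ADF lag order: floor(12*(n/100)^0.25)."""
    return int(math.floor(12.0 * (n / 100.0) ** 0.25))


def adf_test(values: np.ndarray, max_lag_rule: str = "schwert-aic") -> ADFResult:
    """Augmented Dickey-Fuller test with a constant term, no trend.

    Heart-rate windows have a nonzero mean, hence the constant; no
    deterministic trend term is included. The lag order is selected by
    AIC below the Schwert upper bound (``"schwert-aic"``), or fixed at
    the Schwert bound (``"schwert"``).

    A constant window cannot be tested (the regression is singular) and
    is reported as degenerate rather than raising.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError(f"window of length {x.size} too short for ADF (need >= 20)")
    if np.ptp(x) == 0:
        return ADFResult(
            statistic=float("nan"),
            p_value=float("nan"),
            lags_used=0,
            stationary=False,
            degenerate=True,
        )
    maxlag = schwert_max_lag(x.size)
    # keep the regression overdetermined on short windows
    maxlag = min(maxlag, x.size // 2 - 2)
    if max_lag_rule == "schwert-aic":
        stat, p, lags, *_ = adfuller(x, maxlag=maxlag, regression="c", autolag="AIC")
    elif max_lag_rule == "schwert":
        stat, p, lags, *_ = adfuller(x, maxlag=maxlag, regression="c", autolag=None)
    else:
        raise ValueError(f"unknown max_lag_rule: {max_lag_rule!r}")
    return ADFResult(
        statistic=float(stat),
        p_value=float(p),
        lags_used=int(lags),
        stationary=bool(p < SIGNIFICANCE_LEVEL),
    )


def difference(values: np.ndarray, order: int = 1) -> np.ndarray:
    """n-th order differencing: order 1 maps x to x[i+1] - x[i].

    Output is shorter than the input by exactly ``order`` samples.
    """
    x = np.asarray(values, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if x.size <= order:
        raise ValueError(f"series of length {x.size} cannot be differenced {order}x")
    return np.diff(x, n=order)
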