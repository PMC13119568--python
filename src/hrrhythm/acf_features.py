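"""Autocorrelation-function features for heart-rate windows.

Two scalar features per window drive the stress-vs-normal comparison:

* the number of *significant lags* — lags whose autocorrelation exceeds
  the 95% confidence band, a persistence measure;
* the number of *peaks* — strict local maxima of the ACF sequence, a
  roughness measure (white noise has a ragged ACF with many peaks,
  strongly persistent signals a smooth one with few).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "AcfResult",
    "AcfFeatures",
    "autocorrelation",
    "count_significant_lags",
    "count_peaks",
]


@dataclass(frozen=True)
class AcfResult:
    """ACF values with a per-lag 95% significance threshold.

    ``conf_bound[k]`` is the symmetric band at lag k: the constant
    white-noise band 1.96/sqrt(n), or Bartlett's cumulative band when
    requested. ``acf_values[0]`` is always 1.
    """

    lags: np.ndarray
    acf_values: np.ndarray
    conf_bound: np.ndarray
    n_effective: int


@dataclass(frozen=True)
class AcfFeatures:
    n_significant_lags: int
    n_peaks: int
    transform: str  # "actual" | "differenced"


def autocorrelation(
    values: np.ndarray, max_lag: int, band: str = "constant"
) -> AcfResult:
    """Biased-estimator ACF up to ``max_lag`` with a 95% band.

    The estimator normalises lagged covariances by n and by the total
    variance (the standard correlogram convention), so |r_k| <= 1.

    Parameters
    ----------
    values : array-like
        Window samples; length must exceed ``max_lag + 1`` and variance
        must be positive (a flat window has no defined ACF).
    max_lag : int
        Largest lag computed.
    band : {"constant", "bartlett"}
        "constant" uses 1.96/sqrt(n) at every lag; "bartlett" widens the
        band with the cumulative sum of squared lower-lag correlations.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sequence")
    n = x.size
    if n <= max_lag + 1:
        raise ValueError(f"series of length {n} too short for max_lag={max_lag}")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("zero-variance window: ACF undefined (degenerate)")

    r = _sm_acf(x, nlags=max_lag, fft=True, adjusted=False)
    if band == "constant":
        bound = np.full(max_lag + 1, 1.96 / np.sqrt(n))
    elif band == "bartlett":
        # var(r_k) ~ (1 + 2 sum_{j<k} r_j^2)/n
        cum = np.concatenate([[0.0], np.cumsum(r[1:] ** 2)])[: max_lag + 1]
        bound = 1.96 * np.sqrt((1.0 + 2.0 * cum) / n)
    else:
        raise ValueError(f"unknown band type: {band!r}")
    return AcfResult(
        lags=np.arange(max_lag + 1),
        acf_values=r,
        conf_bound=bound,
        n_effective=n,
    )


def count_significant_lags(acf: AcfResult) -> int:
    """Number of lags k >= 1 with |r_k| above the 95% band."""
    return int(np.sum(np.abs(acf.acf_values[1:]) > acf.conf_bound[1:]))


def count_peaks(acf: AcfResult, significant_only: bool = False) -> int:
    """Number of strict local maxima of the ACF sequence.

    A peak is an interior lag k with r[k-1] < r[k] > r[k+1]; ties break
    toward non-peak, keeping the count conservative and deterministic.
    With ``significant_only`` the count is restricted to peaks whose
    |r_k| exceeds the 95% band (the alternative reading of "peaks within
    the confidence interval").
    """
    r = acf.acf_values
    if r.size < 3:
        return 0
    interior = np.arange(1, r.size - 1)
    is_peak = (r[interior] > r[interior - 1]) & (r[interior] > r[interior + 1])
    if significant_only:
        is_peak &= np.abs(r[interior]) > acf.conf_bound[interior]
    return int(np.sum(is_peak))
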