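"""Detrended fluctuation analysis (DFA).

DFA quantifies long-range correlations in a time series. The series is
first integrated into a profile (cumulative sum of deviations from the
mean); the profile is cut into equal-length segments, a low-order
polynomial trend is removed within each segment, and the root-mean-square
residual F(s) is computed per segment size s. The slope alpha of
log F(s) vs log s is the scaling exponent:

* alpha ~ 0.5  : uncorrelated (white) noise
* alpha ~ 1.0  : 1/f (pink) noise, long-range correlated
* alpha ~ 1.5  : Brownian motion (integrated white noise)

Segmentation runs from both ends of the profile (forward and backward)
so that the remainder when the length is not a multiple of the segment
size is still covered; this is the conventional choice and avoids
discarding the tail of short physiological windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DfaResult",
    "integrate_profile",
    "fluctuation_at_scale",
    "default_scales",
    "dfa_alpha",
]

_MIN_LENGTH = 16


@dataclass(frozen=True)
class DfaResult:
    """Outcome of a DFA fit.

    Attributes
    ----------
    scales : np.ndarray
        Segment sizes (samples), strictly increasing.
    fluctuations : np.ndarray
        RMS fluctuation F(s) at each scale, strictly positive.
    alpha : float
        Slope of the ordinary least-squares fit of log10 F on log10 s.
    fit_intercept : float
        Intercept of that fit (log10 units).
    r_squared : float
        Coefficient of determination of the log-log fit.
    """

    scales: np.ndarray
    fluctuations: np.ndarray
    alpha: float
    fit_intercept: float
    r_squared: float
    dropped_scales: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def integrate_profile(values: np.ndarray) -> np.ndarray:
    """Integrate a series into its DFA profile.

    The profile is the cumulative sum of deviations from the series
    mean: ``y[k] = sum_{i<=k} (x[i] - mean(x))``. Its last element is
    zero up to rounding.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sequence")
    if x.size < _MIN_LENGTH:
        raise ValueError(f"series too short for DFA: {x.size} < {_MIN_LENGTH}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return np.cumsum(x - x.mean())


def fluctuation_at_scale(
    profile: np.ndarray, scale: int, detrend_order: int = 1
) -> float:
    """RMS fluctuation of the profile at one segment size.

    The profile is split into ``floor(n/scale)`` non-overlapping segments
    from the start and the same number from the end, so a non-multiple
    remainder is covered once by the backward pass. Each segment is
    detrended by a least-squares polynomial of ``detrend_order`` and the
    residuals of all segments are pooled into a single RMS.
    """
    y = np.asarray(profile, dtype=float)
    n = y.size
    scale = int(scale)
    if not (4 <= scale <= n // 4):
        raise ValueError(f"scale {scale} outside valid range [4, {n // 4}]")
    if detrend_order < 0:
        raise ValueError("detrend_order must be >= 0")

    m = n // scale
    forward = y[: m * scale].reshape(m, scale)
    backward = y[n - m * scale :].reshape(m, scale)
    segments = np.vstack([forward, backward])

    # residual projector for the polynomial design on a common abscissa
    t = np.arange(scale, dtype=float)
    t = (t - t.mean()) / scale  # centred/scaled for conditioning
    design = np.vander(t, detrend_order + 1, increasing=True)
    proj = design @ np.linalg.pinv(design)
    residuals = segments - segments @ proj.T
    return float(np.sqrt(np.mean(residuals**2)))


def default_scales(
    n: int, n_scales: int = 15, min_scale: int = 4, max_scale: int | None = None
) -> np.ndarray:
    """Approximately log-spaced integer segment sizes from 4 to n/4.

    Duplicates arising from integer rounding are removed, so fewer than
    ``n_scales`` distinct scales may be returned for short inputs.
    """
    if max_scale is None:
        max_scale = n // 4
    if max_scale < min_scale:
        raise ValueError("input too short for the requested scale range")
    raw = np.geomspace(min_scale, max_scale, num=n_scales)
    return np.unique(np.round(raw).astype(int))


def dfa_alpha(
    values: np.ndarray,
    scales: np.ndarray | None = None,
    detrend_order: int = 1,
) -> DfaResult:
    """Estimate the DFA scaling exponent of a series.

    Parameters
    ----------
    values : array-like
        Raw (un-integrated) series; integration happens here.
    scales : array-like of int, optional
        Segment sizes. Defaults to ~15 log-spaced integers in
        [4, len/4]. At least 4 scales spanning a factor >= 4 required.
    detrend_order : int
        Polynomial order removed per segment (1 = linear, the usual
        choice for heart-rate windows).

    Returns
    -------
    DfaResult
        Scales, fluctuations, alpha (the log-log slope), intercept and
        R^2 of the fit. Scales with non-finite or zero fluctuation are
        dropped with a warning; fewer than 4 survivors is an error.
    """
    x = np.asarray(values, dtype=float)
    profile = integrate_profile(x)
    if scales is None:
        scales_arr = default_scales(x.size)
    else:
        scales_arr = np.unique(np.asarray(scales, dtype=int))
    if scales_arr.size < 4:
        raise ValueError("need at least 4 distinct scales")
    if scales_arr.max() < 4 * scales_arr.min():
        raise ValueError("scales must span at least a factor of 4")

    flucts = np.array(
        [fluctuation_at_scale(profile, s, detrend_order) for s in scales_arr]
    )
    good = np.isfinite(flucts) & (flucts > 0)
    dropped = scales_arr[~good]
    if dropped.size:
        import warnings

        warnings.warn(
            f"dropping {dropped.size} scale(s) with degenerate fluctuation: "
            f"{dropped.tolist()}",
            stacklevel=2,
        )
    scales_arr, flucts = scales_arr[good], flucts[good]
    if scales_arr.size < 4:
        raise ValueError("fewer than 4 usable scales after dropping degenerates")

    log_s = np.log10(scales_arr)
    log_f = np.log10(flucts)
    slope, intercept = np.polyfit(log_s, log_f, 1)
    fitted = slope * log_s + intercept
    ss_res = np.sum((log_f - fitted) ** 2)
    ss_tot = np.sum((log_f - log_f.mean()) ** 2)
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DfaResult(
        scales=scales_arr,
        fluctuations=flucts,
        alpha=float(slope),
        fit_intercept=float(intercept),
        r_squared=float(r_squared),
        dropped_scales=dropped,
    )
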