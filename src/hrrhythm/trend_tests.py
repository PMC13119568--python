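"""Trend and paired-comparison tests.

The Mann-Kendall test detects monotonic trends without a normality
assumption: the statistic S counts concordant minus discordant ordered
pairs, its variance carries the standard tie correction, and the
normal approximation uses a +/-1 continuity correction. The paired
t-test compares per-participant averages between stress and normal
windows (one difference per participant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TrendTestResult", "PairedComparison", "mann_kendall", "paired_t"]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class TrendTestResult:
    """Mann-Kendall outcome: statistic is the pair-sign sum S."""

    statistic: float
    p_value: float
    direction: str  # "increasing" | "decreasing" | "none"
    n: int
    z: float
    var_s: float
    degenerate: bool = False


@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test on per-participant averages, stress minus normal."""

    parameter_name: str
    mean_normal: float
    mean_stress: float
    t_statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False


def mann_kendall(
    values: np.ndarray, alternative: str = "two-sided"
) -> TrendTestResult:
    """Mann-Kendall monotonic-trend test.

    S = sum over ordered pairs i<j of sign(x[j] - x[i]); under the null
    S is asymptotically normal with tie-corrected variance
    ``(n(n-1)(2n+5) - sum_t t(t-1)(2t+5)) / 18`` summed over tie groups
    of size t. Z applies the +/-1 continuity correction; the p-value is
    two-sided by default (``alternative`` in {"two-sided", "greater",
    "less"} for a one-sided report).

    An all-tied sequence has zero variance and is reported as degenerate
    with S = 0 and p = 1.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in sequence")

    signs = np.sign(x[None, :] - x[:, None])
    s = float(np.sum(np.triu(signs, k=1)))

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0

    if var_s <= 0:
        return TrendTestResult(
            statistic=0.0, p_value=1.0, direction="none", n=n,
            z=0.0, var_s=0.0, degenerate=True,
        )

    if s > 0:
        z = (s - 1.0) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1.0) / np.sqrt(var_s)
    else:
        z = 0.0

    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    p = float(min(p, 1.0))

    if p < SIGNIFICANCE_LEVEL and s > 0:
        direction = "increasing"
    elif p < SIGNIFICANCE_LEVEL and s < 0:
        direction = "decreasing"
    else:
        direction = "none"
    return TrendTestResult(
        statistic=s, p_value=p, direction=direction, n=n, z=float(z),
        var_s=float(var_s),
    )


def paired_t(
    a: np.ndarray,
    b: np.ndarray,
    parameter_name: str = "",
    alternative: str = "two-sided",
) -> PairedComparison:
    """Paired t-test on differences d = a - b.

    ``a`` holds the stress-group values and ``b`` the matched normal
    values, one pair per participant. t = mean(d) / (sd(d)/sqrt(n)) with
    n-1 degrees of freedom. Zero-variance differences (e.g. a == b
    elementwise) are degenerate: no p-value is defined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        return PairedComparison(
            parameter_name=parameter_name,
            mean_normal=float(b.mean()),
            mean_stress=float(a.mean()),
            t_statistic=float("nan"),
            p_value=float("nan"),
            n_pairs=n,
            degenerate=True,
        )
    res = stats.ttest_rel(a, b, alternative=alternative)
    return PairedComparison(
        parameter_name=parameter_name,
        mean_normal=float(b.mean()),
        mean_stress=float(a.mean()),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_pairs=n,
    )
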