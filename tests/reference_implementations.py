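"""Naive reference implementations used as independent oracles.

Deliberately slow and literal: explicit loops, np.polyfit per segment,
pairwise double loops. They share no code with the package paths they
check.
"""

from __future__ import annotations

import numpy as np


def reference_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Double-loop biased ACF estimator: r_k = sum((x_t-m)(x_{t+k}-m)) / (n*var)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    m = x.mean()
    denom = np.sum((x - m) ** 2)
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acc = 0.0
        for t in range(n - k):
            acc += (x[t] - m) * (x[t + k] - m)
        out[k] = acc / denom
    return out


def reference_dfa_fluctuation(
    profile: np.ndarray, scale: int, order: int = 1
) -> float:
    """Per-segment np.polyfit loop, both-ends segmentation, pooled RMS."""
    y = np.asarray(profile, dtype=float)
    n = y.size
    m = n // scale
    sq = []
    starts = [i * scale for i in range(m)] + [n - (i + 1) * scale for i in range(m)]
    for s0 in starts:
        seg = y[s0 : s0 + scale]
        t = np.arange(scale, dtype=float)
        coef = np.polyfit(t, seg, order)
        resid = seg - np.polyval(coef, t)
        sq.extend(resid**2)
    return float(np.sqrt(np.mean(sq)))


def reference_dfa_alpha(
    x: np.ndarray, scales: np.ndarray, order: int = 1
) -> float:
    """Integration, per-scale loop fluctuations, hand OLS on logs."""
    x = np.asarray(x, dtype=float)
    profile = np.cumsum(x - x.mean())
    fl = np.array(
        [reference_dfa_fluctuation(profile, int(s), order) for s in scales]
    )
    ls, lf = np.log10(np.asarray(scales, float)), np.log10(fl)
    ls_c = ls - ls.mean()
    return float(np.sum(ls_c * (lf - lf.mean())) / np.sum(ls_c**2))


def reference_mann_kendall_s(x: np.ndarray) -> int:
    """Exhaustive pair count: concordant minus discordant pairs."""
    x = np.asarray(x, dtype=float)
    s = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if x[j] > x[i]:
                s += 1
            elif x[j] < x[i]:
                s -= 1
    return s
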