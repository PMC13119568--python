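"""Descriptive summaries of a stress-event cohort.

Counts of self-reported events by weekday and hour of day, per-
participant event statistics, and the pooled heart-rate distribution
inside stress windows. Weekday/hour assignment uses each event's local
timestamp; hours are binned by truncation (an event at 18:59 falls in
hour 18). The week starts Monday; weekend = Saturday + Sunday.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from datetime import timedelta

import numpy as np

from .preprocessing import EventWindow, StressEventLog
from .trend_tests import TrendTestResult, mann_kendall

__all__ = [
    "CohortSummary",
    "summarize_cohort",
    "hourly_trend",
    "per_day_rates",
]


@dataclass(frozen=True)
class CohortSummary:
    total_events: int
    n_participants: int
    events_per_participant_mean: float
    events_per_participant_sd: float
    events_per_participant_median: float
    weekday_counts: list[int]  # Monday..Sunday
    hourly_counts: list[int]  # hour 0..23
    stress_hr_mean: float
    stress_hr_sd: float
    stress_hr_median: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_cohort(
    event_logs: list[StressEventLog],
    stress_windows: list[EventWindow] | None = None,
) -> CohortSummary:
    """Aggregate event counts and stress-window heart-rate statistics.

    Per-participant event-count sd is the sample standard deviation
    (ddof=1); for a single participant it is defined as 0. Heart-rate
    statistics pool every sample of every stress window; NaN when no
    windows are supplied.
    """
    if not event_logs:
        raise ValueError("need at least one participant")
    counts = np.array([log.n_events for log in event_logs], dtype=float)
    total = int(counts.sum())

    weekday = np.zeros(7, dtype=int)
    hourly = np.zeros(24, dtype=int)
    for log in event_logs:
        if log.start_time is None:
            raise ValueError(
                f"{log.participant_id}: start_time required for calendar binning"
            )
        for sec in log.event_times:
            ts = log.start_time + timedelta(seconds=float(sec))
            weekday[ts.weekday()] += 1
            hourly[ts.hour] += 1

    if stress_windows:
        hr = np.concatenate([w.values for w in stress_windows])
        hr_mean, hr_sd, hr_median = (
            float(hr.mean()),
            float(hr.std(ddof=1)) if hr.size > 1 else 0.0,
            float(np.median(hr)),
        )
    else:
        hr_mean = hr_sd = hr_median = float("nan")

    sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    return CohortSummary(
        total_events=total,
        n_participants=len(event_logs),
        events_per_participant_mean=float(counts.mean()),
        events_per_participant_sd=sd,
        events_per_participant_median=float(np.median(counts)),
        weekday_counts=weekday.tolist(),
        hourly_counts=hourly.tolist(),
        stress_hr_mean=hr_mean,
        stress_hr_sd=hr_sd,
        stress_hr_median=hr_median,
    )


def per_day_rates(weekday_counts: list[int] | np.ndarray) -> tuple[float, float]:
    """Average events per school day (Mon-Fri) and per weekend day.

    E.g. 1200 weekday events over 5 days vs 313 weekend events over
    2 days give (240.0, 156.5).
    """
    w = np.asarray(weekday_counts, dtype=float)
    if w.size != 7:
        raise ValueError("expected 7 weekday counts (Monday..Sunday)")
    return float(w[:5].sum() / 5.0), float(w[5:].sum() / 2.0)


def hourly_trend(
    hourly_counts: list[int] | np.ndarray,
    span: tuple[int, int],
) -> TrendTestResult:
    """Mann-Kendall trend over hourly event counts restricted to a span.

    ``span`` = (start_hour, end_hour) inclusive, wrapping past midnight
    when end < start (e.g. (18, 6) covers evening through early
    morning). The span must contain at least 4 hours.
    """
    h = np.asarray(hourly_counts, dtype=float)
    if h.size != 24:
        raise ValueError("expected 24 hourly counts")
    start, end = span
    if not (0 <= start <= 23 and 0 <= end <= 23):
        raise ValueError("span hours must lie in 0..23")
    if end >= start:
        hours = list(range(start, end + 1))
    else:
        hours = list(range(start, 24)) + list(range(0, end + 1))
    if len(hours) < 4:
        raise ValueError("span too short for a trend test (need >= 4 hours)")
    return mann_kendall(h[hours])
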