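"""Cleaning and windowing of wearable heart-rate recordings.

The raw signal is a 1 Hz stream where each sample is the average heart
rate over the preceding 60 s. Physiologically implausible samples —
below 60 bpm or above the age-predicted maximum (220 − age) — are
treated as sensor artifacts and removed. Around each self-reported
stress timestamp a 20-minute window (10 min before, 10 min after) is
cut; an equal number of disjoint "normal" windows per participant is
then sampled from the remaining record so the paired comparison is
balanced.

Boundary convention: "below 60" and "above 220 − age" are strict, so a
sample exactly at either bound is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HeartRateSeries",
    "StressEventLog",
    "EventWindow",
    "filter_artifacts",
    "extract_stress_windows",
    "sample_normal_windows",
    "read_samples_csv",
    "read_events_csv",
    "windows_to_frame",
]

LOWER_BPM = 60.0
MAX_HR_BASE = 220.0  # age-predicted maximum = 220 - age
DEFAULT_HALF_WIDTH = 600.0  # seconds, ±10 min
DEFAULT_MIN_COVERAGE = 0.8


@dataclass(frozen=True)
class HeartRateSeries:
    """One participant's timestamped bpm samples.

    ``timestamps`` are seconds since ``start_time`` (strictly
    increasing); ``age`` in years is needed for the artifact filter.
    """

    participant_id: str
    timestamps: np.ndarray
    values: np.ndarray
    age: float
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("timestamps and values must be 1-D and equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class StressEventLog:
    """Self-reported stress timestamps (seconds since ``start_time``)."""

    participant_id: str
    event_times: np.ndarray
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.event_times, dtype=float)
        if e.ndim != 1:
            raise ValueError("event_times must be 1-D")
        if e.size > 1 and not np.all(np.diff(e) >= 0):
            raise ValueError("event_times must be sorted ascending")
        object.__setattr__(self, "event_times", e)

    @property
    def n_events(self) -> int:
        return self.event_times.size


@dataclass(frozen=True)
class EventWindow:
    """A labeled fixed-duration segment — the unit of feature extraction."""

    participant_id: str
    label: str  # "stress" | "normal"
    center_time: float
    values: np.ndarray
    sample_times: np.ndarray = field(repr=False, default=None)
    nominal_length: int = 1200

    def __post_init__(self) -> None:
        if self.label not in ("stress", "normal"):
            raise ValueError(f"label must be 'stress' or 'normal', got {self.label!r}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sample_times is not None:
            object.__setattr__(
                self, "sample_times", np.asarray(self.sample_times, dtype=float)
            )


def filter_artifacts(series: HeartRateSeries) -> tuple[HeartRateSeries, float]:
    """Remove out-of-range samples; return the survivor series and the
    removed fraction.

    Keeps exactly the samples with ``60 <= value <= 220 - age``;
    survivor timestamps are unchanged. An empty series is returned as-is
    with removed fraction 0.
    """
    if not (0 < series.age < 120):
        raise ValueError(f"implausible age: {series.age}")
    n = series.n_samples
    if n == 0:
        return series, 0.0
    upper = MAX_HR_BASE - series.age
    keep = (series.values >= LOWER_BPM) & (series.values <= upper)
    filtered = replace(
        series, timestamps=series.timestamps[keep], values=series.values[keep]
    )
    return filtered, float((n - keep.sum()) / n)


def _window_slice(
    series: HeartRateSeries, center: float, half_width: float
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = center - half_width, center + half_width
    i0, i1 = np.searchsorted(series.timestamps, [lo, hi], side="left")
    # hi is inclusive
    while i1 < series.n_samples and series.timestamps[i1] <= hi:
        i1 += 1
    return series.timestamps[i0:i1], series.values[i0:i1]


def _expected_samples(half_width: float, sample_interval: float) -> int:
    return int(round(2 * half_width / sample_interval)) + 1


def extract_stress_windows(
    series: HeartRateSeries,
    events: StressEventLog,
    half_width: float = DEFAULT_HALF_WIDTH,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    sample_interval: float = 1.0,
) -> list[EventWindow]:
    """Cut one window per stress event from the filtered series.

    A window spans [center − half_width, center + half_width]
    (inclusive). Events within ``half_width`` of the recording boundary,
    and windows holding fewer than ``min_coverage`` of the expected
    samples, are dropped with a warning rather than raising — gaps are a
    fact of wearable data, not an error. Events closer together than a
    window length yield overlapping windows; both are kept.
    """
    if series.n_samples == 0:
        return []
    t0, t1 = series.timestamps[0], series.timestamps[-1]
    expected = _expected_samples(half_width, sample_interval)
    out: list[EventWindow] = []
    for c in events.event_times:
        if c - half_width < t0 or c + half_width > t1:
            warnings.warn(
                f"{series.participant_id}: event at t={c:.0f}s within "
                f"{half_width:.0f}s of a recording boundary; window dropped",
                stacklevel=2,
            )
            continue
        times, vals = _window_slice(series, c, half_width)
        if times.size < min_coverage * expected:
            warnings.warn(
                f"{series.participant_id}: window at t={c:.0f}s has "
                f"{times.size}/{expected} samples (< {min_coverage:.0%} coverage); "
                "dropped",
                stacklevel=2,
            )
            continue
        out.append(
            EventWindow(
                participant_id=series.participant_id,
                label="stress",
                center_time=float(c),
                values=vals,
                sample_times=times,
                nominal_length=expected,
            )
        )
    return out


def sample_normal_windows(
    series: HeartRateSeries,
    events: StressEventLog,
    n: int,
    half_width: float = DEFAULT_HALF_WIDTH,
    seed: int = 0,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    sample_interval: float = 1.0,
    max_attempts_per_window: int = 500,
) -> list[EventWindow]:
    """Sample ``n`` normal windows disjoint from all stress spans.

    Centers are drawn uniformly at random (seeded) from times whose
    window fits inside the recording and overlaps neither a stress
    window span nor a previously accepted normal span. If eligible time
    runs out, as many windows as possible are returned with a warning.
    """
    if n == 0 or series.n_samples == 0:
        return []
    rng = np.random.default_rng(seed)
    t0, t1 = series.timestamps[0], series.timestamps[-1]
    lo, hi = t0 + half_width, t1 - half_width
    if hi <= lo:
        warnings.warn(
            f"{series.participant_id}: recording too short for any normal window",
            stacklevel=2,
        )
        return []
    # spans that a normal window must not touch
    blocked = [(c - half_width, c + half_width) for c in events.event_times]
    expected = _expected_samples(half_width, sample_interval)

    out: list[EventWindow] = []
    attempts = 0
    budget = max_attempts_per_window * n
    while len(out) < n and attempts < budget:
        attempts += 1
        c = rng.uniform(lo, hi)
        w_lo, w_hi = c - half_width, c + half_width
        if any(w_lo <= b_hi and b_lo <= w_hi for b_lo, b_hi in blocked):
            continue
        times, vals = _window_slice(series, c, half_width)
        if times.size < min_coverage * expected:
            continue
        out.append(
            EventWindow(
                participant_id=series.participant_id,
                label="normal",
                center_time=float(c),
                values=vals,
                sample_times=times,
                nominal_length=expected,
            )
        )
        blocked.append((w_lo, w_hi))
    if len(out) < n:
        warnings.warn(
            f"{series.participant_id}: placed only {len(out)}/{n} normal windows "
            "before exhausting eligible time",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# CSV I/O (schema: samples.csv / events.csv as written by synthetic_data)
# ---------------------------------------------------------------------------

def read_samples_csv(path: str | Path, age: float) -> list[HeartRateSeries]:
    """Load per-participant series from a long-format samples.csv.

    Columns: participant_id, timestamp (ISO 8601, treated as local
    naive), heart_rate_bpm. ``age`` applies to every participant (the
    file schema carries no age column).
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp")
        start = grp["timestamp"].iloc[0].to_pydatetime()
        secs = (grp["timestamp"] - grp["timestamp"].iloc[0]).dt.total_seconds()
        out.append(
            HeartRateSeries(
                participant_id=str(pid),
                timestamps=secs.to_numpy(),
                values=grp["heart_rate_bpm"].to_numpy(dtype=float),
                age=age,
                start_time=start,
            )
        )
    return out


def read_events_csv(
    path: str | Path, series_by_id: dict[str, HeartRateSeries] | None = None
) -> list[StressEventLog]:
    """Load per-participant event logs from events.csv.

    Event times are converted to seconds since the matching series'
    start when ``series_by_id`` is given; otherwise since each
    participant's first event.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp")
        pid = str(pid)
        if series_by_id is not None and pid in series_by_id:
            origin = series_by_id[pid].start_time
        else:
            origin = grp["timestamp"].iloc[0].to_pydatetime()
        secs = (grp["timestamp"] - pd.Timestamp(origin)).dt.total_seconds()
        out.append(
            StressEventLog(
                participant_id=pid,
                event_times=secs.to_numpy(),
                start_time=origin,
            )
        )
    return out


def windows_to_frame(windows: list[EventWindow]) -> pd.DataFrame:
    """Long-format table of window samples: one row per sample.

    Columns: participant_id, window_id, label, center_time, offset_s,
    heart_rate_bpm. window_id enumerates windows per participant in
    (label, center) order.
    """
    rows = []
    counter: dict[str, int] = {}
    for w in sorted(windows, key=lambda w: (w.participant_id, w.label, w.center_time)):
        wid = counter.get(w.participant_id, 0)
        counter[w.participant_id] = wid + 1
        offs = (
            w.sample_times - w.center_time
            if w.sample_times is not None
            else np.arange(w.values.size, dtype=float)
        )
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": w.participant_id,
                    "window_id": wid,
                    "label": w.label,
                    "center_time": w.center_time,
                    "offset_s": offs,
                    "heart_rate_bpm": w.values,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "participant_id",
                "window_id",
                "label",
                "center_time",
                "offset_s",
                "heart_rate_bpm",
            ]
        )
    return pd.concat(rows, ignore_index=True)
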