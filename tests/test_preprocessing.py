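"""Artifact filtering and stress/normal windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_events, make_gapless_series
from hrrhythm.preprocessing import (
    HeartRateSeries,
    extract_stress_windows,
    filter_artifacts,
    sample_normal_windows,
    windows_to_frame,
)


def _series(values, age=22.0):
    values = np.asarray(values, dtype=float)
    return HeartRateSeries(
        participant_id="PX",
        timestamps=np.arange(values.size, dtype=float),
        values=values,
        age=age,
    )


class TestFilterArtifacts:
    def test_printed_bounds_age_22(self):
        filtered, frac = filter_artifacts(_series([55.0, 70.0, 210.0], age=22))
        assert filtered.values.tolist() == [70.0]
        assert frac == pytest.approx(2 / 3)

    def test_bounds_are_inclusive(self):
        # "below 60" and "above 220-age" are strict: 60 and 190 survive at age 30
        filtered, frac = filter_artifacts(_series([60.0, 190.0], age=30))
        assert filtered.values.tolist() == [60.0, 190.0]
        assert frac == 0.0

    def test_empty_series(self):
        filtered, frac = filter_artifacts(_series([]))
        assert filtered.n_samples == 0
        assert frac == 0.0

    def test_survivor_timestamps_unchanged(self):
        s = _series([50.0, 80.0, 250.0, 90.0])
        filtered, _ = filter_artifacts(s)
        assert filtered.timestamps.tolist() == [1.0, 3.0]

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.floats(min_value=20, max_value=260, allow_nan=False),
            min_size=0,
            max_size=50,
        )
    )
    def test_idempotence(self, values):
        once, _ = filter_artifacts(_series(values))
        twice, frac = filter_artifacts(once)
        assert np.array_equal(once.values, twice.values)
        assert frac == 0.0

    def test_implausible_age_rejected(self):
        with pytest.raises(ValueError):
            filter_artifacts(_series([80.0], age=0))


class TestExtractStressWindows:
    def test_window_geometry_on_gapless_series(self):
        series = make_gapless_series(20_000)
        wins = extract_stress_windows(series, make_events([5000.0]))
        assert len(wins) == 1
        w = wins[0]
        assert w.values.size == 1201
        assert w.sample_times.min() == 4400.0
        assert w.sample_times.max() == 5600.0

    def test_event_near_boundary_dropped_with_warning(self):
        series = make_gapless_series(20_000)
        with pytest.warns(UserWarning, match="boundary"):
            wins = extract_stress_windows(series, make_events([100.0]))
        assert wins == []

    def test_close_events_yield_overlapping_windows(self):
        series = make_gapless_series(20_000)
        wins = extract_stress_windows(series, make_events([5000.0, 5300.0]))
        assert len(wins) == 2

    def test_low_coverage_window_dropped(self):
        t = np.concatenate([np.arange(0, 4500.0), np.arange(5500.0, 9000.0)])
        series = HeartRateSeries("PX", t, np.full(t.size, 80.0), age=22)
        with pytest.warns(UserWarning, match="coverage"):
            wins = extract_stress_windows(series, make_events([5000.0]))
        assert wins == []


class TestSampleNormalWindows:
    def test_zero_requested_gives_empty(self):
        series = make_gapless_series(20_000)
        assert sample_normal_windows(series, make_events([5000.0]), n=0) == []

    def test_disjoint_from_stress_span_exhaustively(self):
        series = make_gapless_series(20_000)
        events = make_events([5000.0])
        wins = sample_normal_windows(series, events, n=1, seed=7)
        assert len(wins) == 1
        assert not np.any(
            (wins[0].sample_times >= 4400.0) & (wins[0].sample_times <= 5600.0)
        )

    def test_seed_reproducibility(self):
        series = make_gapless_series(20_000)
        events = make_events([5000.0])
        a = sample_normal_windows(series, events, n=1, seed=7)
        b = sample_normal_windows(series, events, n=1, seed=7)
        c = sample_normal_windows(series, events, n=1, seed=8)
        assert a[0].center_time == b[0].center_time
        assert a[0].center_time != c[0].center_time

    def test_normal_windows_mutually_disjoint(self):
        series = make_gapless_series(40_000)
        events = make_events([5000.0, 15_000.0])
        wins = sample_normal_windows(series, events, n=4, seed=3)
        assert len(wins) == 4
        spans = sorted(
            (w.center_time - 600.0, w.center_time + 600.0) for w in wins
        )
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            assert lo > hi

    def test_insufficient_room_warns_and_returns_partial(self):
        series = make_gapless_series(5000)
        events = make_events([2500.0])
        with pytest.warns(UserWarning, match="placed only"):
            wins = sample_normal_windows(series, events, n=5, seed=1)
        assert len(wins) < 5


class TestWindowsToFrame:
    def test_long_format_columns_and_offsets(self):
        series = make_gapless_series(20_000)
        wins = extract_stress_windows(series, make_events([5000.0]))
        df = windows_to_frame(wins)
        assert list(df.columns) == [
            "participant_id", "window_id", "label", "center_time",
            "offset_s", "heart_rate_bpm",
        ]
        assert df["offset_s"].min() == -600.0
        assert df["offset_s"].max() == 600.0
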