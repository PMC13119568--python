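"""Descriptive summary of the simulated cohort.

Event counts per participant, weekday/weekend per-day rates, hourly
distribution with Mann-Kendall trends over the daytime (06-18) and
nighttime (18-06) spans, and the pooled heart-rate distribution inside
stress windows. Writes results/summary.json. The default generator
places events uniformly in time, so — unlike a real student cohort —
no diurnal trend is expected here; the trend tests simply report what
the data contain.
"""

import json
from pathlib import Path

from hrrhythm.descriptive import hourly_trend, per_day_rates, summarize_cohort
from hrrhythm.preprocessing import read_events_csv, read_samples_csv

import importlib.util

_spec = importlib.util.spec_from_file_location(
    "extract_features", Path(__file__).parent / "03_extract_features.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_windows = _mod.load_windows

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    series_list = read_samples_csv(RESULTS / "cohort" / "samples.csv", age=22.0)
    logs = read_events_csv(
        RESULTS / "cohort" / "events.csv",
        {s.participant_id: s for s in series_list},
    )
    stress_windows = [
        w for w in load_windows(RESULTS / "windows.csv") if w.label == "stress"
    ]
    summary = summarize_cohort(logs, stress_windows)
    (RESULTS / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    school, weekend = per_day_rates(summary.weekday_counts)
    day = hourly_trend(summary.hourly_counts, (6, 18))
    night = hourly_trend(summary.hourly_counts, (18, 6))
    print(f"{summary.total_events} events from {summary.n_participants} "
          f"participants (mean {summary.events_per_participant_mean:.1f}, "
          f"sd {summary.events_per_participant_sd:.2f}, "
          f"median {summary.events_per_participant_median:.0f})")
    print(f"per-day rates: school days {school:.1f}, weekend {weekend:.1f}")
    print(f"stress-window HR: mean {summary.stress_hr_mean:.1f} bpm, "
          f"sd {summary.stress_hr_sd:.2f}, median {summary.stress_hr_median:.2f}")
    print(f"06-18 trend: {day.direction} (p={day.p_value:.3f}); "
          f"18-06 trend: {night.direction} (p={night.p_value:.3f})")
    print(f"wrote {RESULTS / 'summary.json'}")


if __name__ == "__main__":
    main()
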