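"""End-to-end orchestration: simulate or ingest, preprocess, test
stationarity, extract ACF and DFA features, and compare stress vs
normal windows participant-by-participant.

The comparison follows the protocol's pairing: features are averaged
per participant within each label first, and the paired t-test runs on
those per-participant averages (one stress/normal pair per
participant). ACF features are compared on the differenced transform
(the correlogram is only valid on stationary data); the DFA scaling
exponent is compared on the actual signal, since DFA does not require
stationarity and differencing would destroy the profile it integrates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acf_features import autocorrelation, count_peaks, count_significant_lags
from .descriptive import CohortSummary, summarize_cohort
from .dfa import dfa_alpha
from .preprocessing import (
    EventWindow,
    HeartRateSeries,
    StressEventLog,
    extract_stress_windows,
    filter_artifacts,
    read_events_csv,
    read_samples_csv,
    sample_normal_windows,
    windows_to_frame,
)
from .stationarity import adf_test, difference
from .synthetic_data import SimulationConfig, generate_cohort
from .trend_tests import PairedComparison, paired_t

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "extract_window_features",
    "build_feature_table",
    "build_comparison_report",
    "run_pipeline",
]

#: report rows: (parameter, source column, transform the t-test uses)
_REPORT_PARAMS = [
    ("Number of significant lags", "n_significant_lags", "differenced"),
    ("Number of peaks", "n_peaks", "differenced"),
    ("Scaling Exponent (Alpha)", "alpha", "actual"),
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run.

    Either ``simulation`` (a SimulationConfig) or both ``samples_path``
    and ``events_path`` must be given. ``dfa_span`` selects the segment
    DFA sees: "post_event" (default) uses ``dfa_samples`` samples
    starting at the window center — the five minutes after the reported
    stress moment — while "full" uses the whole window.
    """

    simulation: SimulationConfig | None = None
    samples_path: str | None = None
    events_path: str | None = None
    age: float = 22.0
    half_width: float = 600.0
    min_coverage: float = 0.8
    sample_interval: float = 1.0
    max_lag: int = 600
    band: str = "constant"
    peaks_significant_only: bool = False
    dfa_span: str = "post_event"  # "post_event" | "full"
    dfa_samples: int = 300
    detrend_order: int = 1
    adf_rule: str = "schwert-aic"
    significance_level: float = 0.05
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.simulation is None and not (self.samples_path and self.events_path):
            raise ValueError(
                "config needs either a simulation block or samples/events paths"
            )
        if self.dfa_span not in ("post_event", "full"):
            raise ValueError(f"unknown dfa_span: {self.dfa_span!r}")


@dataclass
class PipelineResult:
    features: pd.DataFrame
    report: pd.DataFrame
    comparisons: list[PairedComparison]
    summary: CohortSummary | None
    manifest: dict
    windows: list[EventWindow] = field(default_factory=list)


def _dfa_segment(window: EventWindow, config: PipelineConfig) -> np.ndarray:
    if config.dfa_span == "full":
        return window.values
    lo = window.center_time
    hi = lo + config.dfa_samples * config.sample_interval
    mask = (window.sample_times >= lo) & (window.sample_times < hi)
    return window.values[mask]


def extract_window_features(
    window: EventWindow, config: PipelineConfig
) -> list[dict]:
    """Feature rows (one per transform) for a single window.

    Each row carries the ADF result of the actual signal, the ACF
    feature pair for its transform, and — on the actual transform only —
    the DFA scaling exponent of the configured span. Degenerate windows
    (zero variance) yield NaN features and a flag instead of an error.
    """
    rows = []
    actual = window.values
    adf = None
    if actual.size >= 20 and np.ptp(actual) > 0:
        adf = adf_test(actual, config.adf_rule)

    for transform in ("actual", "differenced"):
        x = actual if transform == "actual" else np.diff(actual)
        row = {
            "participant_id": window.participant_id,
            "label": window.label,
            "center_time": window.center_time,
            "transform": transform,
            "n_samples": int(x.size),
            "adf_statistic": adf.statistic if (adf and transform == "actual") else np.nan,
            "adf_p": adf.p_value if (adf and transform == "actual") else np.nan,
            "stationary": adf.stationary if (adf and transform == "actual") else None,
            "n_significant_lags": np.nan,
            "n_peaks": np.nan,
            "alpha": np.nan,
            "r_squared": np.nan,
            "n_scales": 0,
            "degenerate": False,
        }
        max_lag = min(config.max_lag, x.size - 2)
        try:
            acf = autocorrelation(x, max_lag=max_lag, band=config.band)
            row["n_significant_lags"] = count_significant_lags(acf)
            row["n_peaks"] = count_peaks(
                acf, significant_only=config.peaks_significant_only
            )
        except ValueError:
            row["degenerate"] = True

        if transform == "actual":
            seg = _dfa_segment(window, config)
            if seg.size >= 64 and np.ptp(seg) > 0:
                try:
                    res = dfa_alpha(seg, detrend_order=config.detrend_order)
                    row["alpha"] = res.alpha
                    row["r_squared"] = res.r_squared
                    row["n_scales"] = int(res.scales.size)
                except ValueError:
                    row["degenerate"] = True
        rows.append(row)
    return rows


def build_feature_table(
    windows: list[EventWindow], config: PipelineConfig
) -> pd.DataFrame:
    """Per-window feature table over both transforms, with window ids."""
    rows: list[dict] = []
    counter: dict[str, int] = {}
    for w in sorted(windows, key=lambda w: (w.participant_id, w.label, w.center_time)):
        wid = counter.get(w.participant_id, 0)
        counter[w.participant_id] = wid + 1
        for row in extract_window_features(w, config):
            row["window_id"] = wid
            rows.append(row)
    cols = [
        "participant_id", "window_id", "label", "transform", "center_time",
        "n_samples", "adf_statistic", "adf_p", "stationary",
        "n_significant_lags", "n_peaks", "alpha", "r_squared", "n_scales",
        "degenerate",
    ]
    return pd.DataFrame(rows, columns=cols)


def build_comparison_report(
    features: pd.DataFrame,
) -> tuple[pd.DataFrame, list[PairedComparison]]:
    """Stress-vs-normal comparison table from a per-window feature table.

    Features are averaged per participant within each (label, transform)
    cell; each parameter's paired t-test then pairs the per-participant
    stress and normal averages on the transform noted in the table
    (differenced for the ACF features, actual for alpha). Participants
    missing either label for a parameter drop out of that row's pairing.
    """
    rows, comparisons = [], []
    for name, column, test_transform in _REPORT_PARAMS:
        sub = features[features["transform"] == test_transform]
        per_part = (
            sub.groupby(["participant_id", "label"])[column].mean().unstack("label")
        )
        means = {}
        for transform in ("actual", "differenced"):
            tsub = features[features["transform"] == transform]
            m = tsub.groupby("label")[column].mean()
            means[transform] = (m.get("normal", np.nan), m.get("stress", np.nan))

        if {"stress", "normal"} <= set(per_part.columns):
            paired = per_part.dropna(subset=["stress", "normal"])
        else:
            paired = pd.DataFrame(columns=["stress", "normal"])
        if len(paired) >= 2:
            cmp_res = paired_t(
                paired["stress"].to_numpy(),
                paired["normal"].to_numpy(),
                parameter_name=name,
            )
        else:
            cmp_res = PairedComparison(
                parameter_name=name,
                mean_normal=means[test_transform][0],
                mean_stress=means[test_transform][1],
                t_statistic=float("nan"),
                p_value=float("nan"),
                n_pairs=len(paired),
                degenerate=True,
            )
        comparisons.append(cmp_res)
        is_alpha = column == "alpha"
        rows.append(
            {
                "parameter": name,
                "test_transform": test_transform,
                "t_statistic": cmp_res.t_statistic,
                "p_value": cmp_res.p_value,
                "n_pairs": cmp_res.n_pairs,
                "mean_normal_actual": means["actual"][0],
                "mean_stress_actual": means["actual"][1],
                "mean_normal_differenced": np.nan if is_alpha else means["differenced"][0],
                "mean_stress_differenced": np.nan if is_alpha else means["differenced"][1],
            }
        )
    return pd.DataFrame(rows), comparisons


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run simulate/ingest → filter → window → features → compare.

    Writes windows.csv, features.csv, report.csv/.json, summary.json
    and manifest.json when ``config.outdir`` is set. Reruns with the
    same config and seed are bit-identical.
    """
    if config.simulation is not None:
        series_list, logs = generate_cohort(config.simulation)
    else:
        series_list = read_samples_csv(config.samples_path, age=config.age)
        by_id = {s.participant_id: s for s in series_list}
        logs = read_events_csv(config.events_path, by_id)
    logs_by_id = {log.participant_id: log for log in logs}

    windows: list[EventWindow] = []
    removed_fractions: dict[str, float] = {}
    excluded: list[str] = []
    rng = np.random.default_rng(config.seed)
    for series in series_list:
        filtered, removed = filter_artifacts(series)
        removed_fractions[series.participant_id] = removed
        log = logs_by_id.get(
            series.participant_id,
            StressEventLog(series.participant_id, np.array([]), series.start_time),
        )
        stress = extract_stress_windows(
            filtered, log,
            half_width=config.half_width,
            min_coverage=config.min_coverage,
            sample_interval=config.sample_interval,
        )
        normal = sample_normal_windows(
            filtered, log, n=len(stress),
            half_width=config.half_width,
            seed=int(rng.integers(0, 2**31 - 1)),
            min_coverage=config.min_coverage,
            sample_interval=config.sample_interval,
        )
        if not stress:
            excluded.append(series.participant_id)
        windows.extend(stress)
        windows.extend(normal)

    features = build_feature_table(windows, config)
    stress_windows = [w for w in windows if w.label == "stress"]
    summary = summarize_cohort(logs, stress_windows) if logs else None

    if stress_windows:
        report, comparisons = build_comparison_report(features)
    else:
        warnings.warn("no stress windows retained; comparison stage skipped",
                      stacklevel=2)
        report, comparisons = pd.DataFrame(), []

    import scipy
    import statsmodels

    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "versions": {
            "hrrhythm": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "stage_counts": {
            "participants": len(series_list),
            "stress_windows": len(stress_windows),
            "normal_windows": len(windows) - len(stress_windows),
            "feature_rows": len(features),
        },
        "removed_fraction_by_participant": removed_fractions,
        "participants_excluded_from_pairing": excluded,
    }

    result = PipelineResult(
        features=features, report=report, comparisons=comparisons,
        summary=summary, manifest=manifest, windows=windows,
    )
    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d.pop("outdir", None)  # self-referential; irrelevant to reproducibility
    return d


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    windows_to_frame(result.windows).to_csv(outdir / "windows.csv", index=False)
    result.features.to_csv(outdir / "features.csv", index=False)
    result.report.to_csv(outdir / "report.csv", index=False)
    (outdir / "report.json").write_text(
        result.report.to_json(orient="records", indent=2) + "\n"
    )
    if result.summary is not None:
        (outdir / "summary.json").write_text(
            json.dumps(result.summary.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
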