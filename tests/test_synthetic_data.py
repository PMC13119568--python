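"""Generator contracts: determinism, alpha targeting, artifacts, events."""

import numpy as np
import pytest

from hrrhythm.dfa import dfa_alpha
from hrrhythm.preprocessing import filter_artifacts
from hrrhythm.synthetic_data import (
    SimulationConfig,
    generate_cohort,
    generate_long_range_noise,
    generate_participant,
    write_cohort_csv,
)


class TestLongRangeNoise:
    def test_zero_mean_unit_variance(self):
        x = generate_long_range_noise(4096, 1.0, seed=3)
        assert x.mean() == pytest.approx(0.0, abs=1e-12)
        assert x.std() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5])
    def test_dfa_recovers_target_exponent(self, alpha):
        ests = [
            dfa_alpha(generate_long_range_noise(2**13, alpha, seed=s)).alpha
            for s in range(8)
        ]
        assert np.mean(ests) == pytest.approx(alpha, abs=0.08)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            generate_long_range_noise(1024, 0.3, seed=0)
        with pytest.raises(ValueError, match="alpha"):
            generate_long_range_noise(1024, 1.7, seed=0)

    def test_seed_determinism(self):
        a = generate_long_range_noise(1024, 0.8, seed=5)
        b = generate_long_range_noise(1024, 0.8, seed=5)
        assert np.array_equal(a, b)


class TestSimulationConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration=1000.0, episode_half_width=600.0)
        with pytest.raises(ValueError):
            SimulationConfig(artifact_rate=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(normal_alpha=0.2)


class TestGenerateParticipant:
    def test_identical_config_and_seed_identical_output(self, small_sim_config):
        s1, e1 = generate_participant(small_sim_config, "P001")
        s2, e2 = generate_participant(small_sim_config, "P001")
        assert np.array_equal(s1.values, s2.values)
        assert np.array_equal(e1.event_times, e2.event_times)

    def test_different_participants_differ(self, small_sim_config):
        s1, _ = generate_participant(small_sim_config, "P001")
        s2, _ = generate_participant(small_sim_config, "P002")
        assert not np.array_equal(s1.values, s2.values)

    def test_degenerate_config_no_events_no_artifacts(self):
        cfg = SimulationConfig(
            duration=4000.0, events_per_participant=0, artifact_rate=0.0,
            baseline_bpm=90.0, circadian_amplitude=5.0, noise_sd=3.0, seed=1,
        )
        series, log = generate_participant(cfg, "P001")
        assert log.n_events == 0
        # clean signal stays well inside the physiological filter band
        assert series.values.min() > 60.0
        assert series.values.max() < 220.0 - cfg.age

    def test_artifact_fraction_matches_filter_removal(self):
        cfg = SimulationConfig(
            duration=10_000.0, events_per_participant=0, artifact_rate=0.05,
            baseline_bpm=90.0, circadian_amplitude=5.0, noise_sd=3.0, seed=2,
        )
        series, _ = generate_participant(cfg, "P001")
        _, removed = filter_artifacts(series)
        assert removed == pytest.approx(0.05, abs=0.005)

    def test_events_spaced_beyond_window_diameter(self):
        cfg = SimulationConfig(
            duration=30_000.0, events_per_participant=3, seed=4
        )
        _, log = generate_participant(cfg, "P001")
        assert log.n_events == 3
        assert np.all(np.diff(log.event_times) > 2 * cfg.episode_half_width)

    def test_impossible_event_placement_rejected(self):
        cfg = SimulationConfig(
            duration=3000.0, events_per_participant=10, episode_half_width=600.0
        )
        with pytest.raises(ValueError, match="place"):
            generate_participant(cfg, "P001")

    def test_stress_windows_have_elevated_mean(self):
        # averages over >= 20 injected events across participants
        cfg = SimulationConfig(
            n_participants=5, duration=28_800.0, events_per_participant=5,
            stress_mean_shift=8.0, artifact_rate=0.0, seed=6,
        )
        series_list, logs = generate_cohort(cfg)
        stress_means, normal_means = [], []
        hw = cfg.episode_half_width
        for s, log in zip(series_list, logs):
            inside = np.zeros(s.n_samples, dtype=bool)
            for c in log.event_times:
                inside |= np.abs(s.timestamps - c) <= hw
            stress_means.append(s.values[inside].mean())
            normal_means.append(s.values[~inside].mean())
        assert len(logs) * cfg.events_per_participant >= 20
        assert np.mean(stress_means) > np.mean(normal_means) + 0.5 * cfg.stress_mean_shift


class TestCsvRoundTrip:
    def test_byte_identical_rerun(self, tmp_path, small_sim_config):
        series, logs = generate_cohort(small_sim_config)
        p1 = tmp_path / "a"
        p2 = tmp_path / "b"
        write_cohort_csv(series, logs, p1, config=small_sim_config)
        write_cohort_csv(series, logs, p2, config=small_sim_config)
        for name in ("samples.csv", "events.csv", "simulation.json"):
            assert (p1 / name).read_bytes() == (p2 / name).read_bytes()

    def test_schema(self, tmp_path, small_sim_config):
        import pandas as pd

        series, logs = generate_cohort(small_sim_config)
        samples, events = write_cohort_csv(series, logs, tmp_path)
        sdf = pd.read_csv(samples)
        edf = pd.read_csv(events)
        assert list(sdf.columns) == ["participant_id", "timestamp", "heart_rate_bpm"]
        assert list(edf.columns) == ["participant_id", "timestamp"]
        # ISO-8601 local-naive timestamps
        pd.to_datetime(sdf["timestamp"].head())
        assert len(edf) == sum(log.n_events for log in logs)
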