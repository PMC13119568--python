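import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hrrhythm.preprocessing import HeartRateSeries, StressEventLog
from hrrhythm.synthetic_data import SimulationConfig, generate_participant


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale participant: 4 h recording, 3 stress episodes."""
    return SimulationConfig(
        n_participants=1,
        duration=14_400.0,
        events_per_participant=3,
        normal_alpha=0.7,
        stress_alpha=1.0,
        stress_mean_shift=8.0,
        artifact_rate=0.03,
        seed=42,
    )


@pytest.fixture(scope="session")
def simulated_participant(small_sim_config):
    return generate_participant(small_sim_config, "P001")


def make_gapless_series(
    duration: float = 20_000.0, age: float = 22.0, value: float = 80.0
) -> HeartRateSeries:
    t = np.arange(duration)
    return HeartRateSeries(
        participant_id="PX",
        timestamps=t,
        values=np.full(t.size, value) + 0.1 * np.sin(t / 50.0),
        age=age,
    )


def make_events(times, pid="PX") -> StressEventLog:
    return StressEventLog(participant_id=pid, event_times=np.asarray(times, float))
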