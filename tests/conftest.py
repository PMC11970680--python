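import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from actisleep import EpochSeries, SleepWakeSeries

T0 = pd.Timestamp("2024-03-01 12:00")


def make_series(counts, pid="P01", start=T0, wear=None) -> EpochSeries:
    return EpochSeries(pid, start, np.asarray(counts, dtype=np.int64), wear)


def make_sw(states, pid="P01", start=T0) -> SleepWakeSeries:
    """Build a SleepWakeSeries from an iterable of 0/1 or a string of 'S'/'W'."""
    if isinstance(states, str):
        states = [1 if c == "S" else 0 for c in states]
    return SleepWakeSeries(pid, start, np.asarray(states, dtype=np.int8))


def random_state_series(rng, n):
    """Random sleep/wake states with realistic run structure, plus counts."""
    states = np.zeros(n, dtype=np.int8)
    i = 0
    asleep = bool(rng.integers(0, 2))
    while i < n:
        run = int(rng.geometric(rng.uniform(0.01, 0.3)))
        states[i : i + run] = 1 if asleep else 0
        i += run
        asleep = not asleep
    counts = np.where(
        states == 0, rng.integers(0, 400, n), (rng.random(n) < 0.15).astype(int)
    ).astype(np.int64)
    return states, counts


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-participant restless cohort shared by slower integration tests."""
    from actisleep import CohortSpec, generate_cohort

    spec = CohortSpec(n_participants=4, nights_per_participant=5, seed=7)
    return generate_cohort(spec)
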