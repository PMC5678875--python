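import numpy as np
import pytest

from fanova_activity.epochs import EpochSeries
from fanova_activity.simulate import SimulationConfig, simulate_minute_profiles


def make_minute_series(minutes, counts=None, child="C1", date="2008-03-03"):
    """Minute-level series from a list of minute-of-day start times."""
    minutes = np.asarray(sorted(minutes), dtype=np.int64)
    if counts is None:
        counts = np.full(minutes.size, 100, dtype=np.int64)
    return EpochSeries(child_id=child, date=date, starts=minutes * 60,
                       epoch_seconds=60, counts=counts)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-child simulated cohort with the default ground-truth effects."""
    config = SimulationConfig(n_children=30)
    Y, cov, truth = simulate_minute_profiles(config, seed=2024)
    return Y, cov, truth
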