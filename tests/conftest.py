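import numpy as np
import pytest

from robsel.data_io import SurvivalOutcome
from robsel.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def signal_dataset():
    """Moderate-size cohort with a strong 5-feature signal (shared, read-only)."""
    return simulate_dataset(SimulationConfig(n=120, p=100, s=5, effect_size=1.5, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_outcome(rng, n, censor_frac=0.4, with_ties=False):
    """Helper for metric tests: arbitrary censored outcomes, optional ties."""
    times = rng.exponential(1.0, n) + 0.05
    if with_ties:
        times = np.round(times, 1) + 0.05
    events = (rng.uniform(size=n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[int(np.argmin(times))] = 1
    return SurvivalOutcome(times, events)
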