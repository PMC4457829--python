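import numpy as np
import pytest

from pgbkinetics import ExperimentConditions, log_times, preset


@pytest.fixture(scope="session")
def wt():
    return preset("wt")


@pytest.fixture
def cond_1atm():
    return ExperimentConditions(co_pressure=1.0)


@pytest.fixture
def cond_01atm():
    return ExperimentConditions(co_pressure=0.1)


@pytest.fixture
def scavenger_conditions():
    return ExperimentConditions(co_pressure=0.0, scavenger_mode=True)


@pytest.fixture(scope="session")
def coarse_times():
    """A light log grid for tests that only need trajectory shape."""
    return log_times(1e-8, 1.0, per_decade=25)


def random_rate_set(rng) -> dict:
    """Log-uniform random rate constants in physically plausible ranges."""
    from pgbkinetics import RATE_FIELDS

    values = {}
    for name in RATE_FIELDS:
        if name in ("kin_r", "kin_t"):
            values[name] = 10.0 ** rng.uniform(6, 9)
        elif name in ("kdiss_r", "kdiss_t"):
            values[name] = 10.0 ** rng.uniform(-2, 0)
        else:
            values[name] = 10.0 ** rng.uniform(3, 8)
    return values
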