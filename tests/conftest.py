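import numpy as np
import pytest

from hitchsim.model import ClassTable, SimulationParams


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams()


@pytest.fixture(scope="session")
def default_table(default_params):
    return ClassTable(default_params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fast_params():
    """Small, quick serial-passage regime for structural tests.

    A 100-fold dilution (1e3 of 1e5) and a 100-fold-raised beneficial rate
    keep full trials in the low-millisecond range while preserving the
    growth/bottleneck architecture.
    """
    return SimulationParams(
        mu_b=1e-5,
        n_max=1e5,
        n_bottleneck=1_000,
        est_threshold=20,
        max_generations=3_000,
    )
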