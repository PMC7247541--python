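import numpy as np
import pytest

from epimsap.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study: 38 samples, 120 epiloci, 10 populations."""
    return SimulationConfig(
        group_sizes={"2xS": 12, "2xM": 4, "4xM": 12, "4xA": 10},
        panel_sizes={"n": 30, "e": 40, "i": 50},
        n_populations=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_study):
    """Scorable expanded binary matrix of the small study."""
    return small_study.states.expanded(drop_unobserved=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
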