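import numpy as np
import pytest

from hhwave import PathwayParameters, SimulationConfig, SourceDescriptor, run_simulation

BATTERY_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def default_params():
    return PathwayParameters()


@pytest.fixture(scope="session")
def battery_traces(default_params):
    """Five standard static-source runs to steady state, shared across tests."""
    traces = {}
    for seed in BATTERY_SEEDS:
        cfg = SimulationConfig(params=default_params,
                               source=SourceDescriptor(alpha1=default_params.alpha1),
                               seed=seed)
        traces[seed] = run_simulation(cfg)
    return traces


@pytest.fixture(scope="session")
def static_trace(battery_traces):
    return battery_traces[1]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
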