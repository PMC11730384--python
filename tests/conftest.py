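import numpy as np
import pytest

from gliamass import (SimulationConfig, default_parameters, run_simulation,
                      default_initial_state, surrogate_layers)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def small_layers():
    return surrogate_layers(8, seed=11)


@pytest.fixture(scope="session")
def short_run(params, small_layers):
    """A short stochastic 8-node run shared by analysis tests (30 s)."""
    cfg = SimulationConfig(duration=30.0, seed=5)
    init = default_initial_state(params, small_layers.n_nodes)
    return run_simulation(init, cfg, small_layers, params)
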