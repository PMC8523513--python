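import numpy as np
import pytest

from jitaisim import (SimulatorConfig, SyntheticWorldParams,
                      fit_context_distribution, generate_activity_log,
                      generate_weather_stream)


@pytest.fixture(scope="session")
def world_params():
    return SyntheticWorldParams()


@pytest.fixture(scope="session")
def small_world(world_params):
    """Desk-scale synthetic world: (activity_log, weather_stream)."""
    log = generate_activity_log(world_params, 4000, np.random.default_rng(101))
    stream = generate_weather_stream(world_params, 24 * 120,
                                     np.random.default_rng(102))
    return log, stream


@pytest.fixture(scope="session")
def fitted_models(small_world):
    log, stream = small_world
    return fit_context_distribution(log), fit_context_distribution(stream)


@pytest.fixture(scope="session")
def sim_config():
    return SimulatorConfig()
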