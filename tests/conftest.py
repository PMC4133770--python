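import numpy as np
import pytest

from cerebarm.arm import default_arm
from cerebarm.control import ExperimentConfig, IOEncodingSpec, NetworkConfig
from cerebarm.network import WeightSet


@pytest.fixture(scope="session")
def arm():
    return default_arm()


@pytest.fixture(scope="session")
def small_net():
    """Scaled-down granular clock: 50 states at 10 ms over a 0.5 s trial."""
    return NetworkConfig(dt=0.01, trial_duration=0.5)


@pytest.fixture
def small_cfg(small_net):
    """Fast closed-loop configuration with explicit calibrations."""
    return ExperimentConfig(
        payload_kg=2.0,
        n_trials=3,
        network=small_net,
        io_encoding=IOEncodingSpec(e_sat=0.5, delay_steps=3),
        output_gain=100.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20140815)


@pytest.fixture
def op_weights(small_net):
    return WeightSet.operating_point(small_net)
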