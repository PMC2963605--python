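import numpy as np
import pytest

from grninfer import (
    GRNInference,
    SimulationConfig,
    generate_topology,
    simulate_dream4_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """10-gene noisy dataset shared by read-only tests."""
    net = generate_topology(10, 2.0, seed=11)
    return simulate_dream4_dataset(net, SimulationConfig(seed=12))


@pytest.fixture(scope="session")
def small_noiseless_dataset():
    net = generate_topology(10, 2.0, seed=21)
    cfg = SimulationConfig(seed=22, noise_coeff=0.0, noise_floor=0.0)
    return simulate_dream4_dataset(net, cfg)


@pytest.fixture(scope="session")
def small_model(small_dataset):
    return GRNInference(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
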