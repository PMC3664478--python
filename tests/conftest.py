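import numpy as np
import pytest

from ckfsnet import GeneNetwork, NoiseConfig, generate_network, simulate


@pytest.fixture(scope="session")
def benchmark_network():
    """The 8-gene / 20-edge benchmark topology."""
    return generate_network(8, 20, seed=0)


@pytest.fixture(scope="session")
def benchmark_data(benchmark_network):
    """Five perturbation series of 40 points from the benchmark network."""
    return simulate(benchmark_network, 40, NoiseConfig(), seed=1, n_series=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_psd(rng, n, scale=1.0):
    A = rng.normal(size=(n, n))
    return scale * (A @ A.T / n + 0.1 * np.eye(n))
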