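import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from distressnet.synthetic import CohortConfig, make_true_network, sample_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


# sparse five-block ground truth mirroring the frozen-node layout
from distressnet.benchmarks import frozen_node_network_spec as sixteen_node_spec  # noqa: E402


@pytest.fixture(scope="session")
def sixteen_node_truth() -> np.ndarray:
    return make_true_network(sixteen_node_spec())


@pytest.fixture(scope="session")
def small_cohort():
    return sample_cohort(CohortConfig(n=200, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def chain_correlation() -> np.ndarray:
    """AR(1)-style 3-variable chain: 1-2 and 2-3 linked, 1-3 only through 2,
    so the 1-3 partial correlation is exactly zero."""
    r = 0.6
    return np.array([[1.0, r, r * r], [r, 1.0, r], [r * r, r, 1.0]])
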