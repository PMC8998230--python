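import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gonogo import NetworkParams, PlasticWeights
from gonogo.experiments import calibrated_network


@pytest.fixture(scope="session")
def net2():
    """Calibrated two-channel network (shared; treat as read-only)."""
    return calibrated_network(2)


@pytest.fixture(scope="session")
def net4():
    return calibrated_network(4)


@pytest.fixture()
def naive_weights(net2):
    return PlasticWeights.naive(2, 2, net2.params)


@pytest.fixture()
def trained_weights(net2):
    """Hand-set weights mimicking a well-trained two-choice agent."""
    w = PlasticWeights.naive(2, 2, net2.params)
    w.w_gs = np.array([[0.8, 0.05], [0.05, 0.8]])
    w.w_ns = np.array([[0.45, 0.25], [0.25, 0.45]])
    w.w_gc = np.eye(2) * 0.8
    w.w_nc = np.eye(2) * (net2.params.w_nc0 + 0.05)
    return w


@pytest.fixture()
def stimulus():
    return np.array([1.0, 0.3])
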