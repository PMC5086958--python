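import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tmseeg.montage import build_neighbor_graph, default_montage

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def graph(montage):
    return build_neighbor_graph(montage)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
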