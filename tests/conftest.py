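import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bipnest import BipartiteNetwork

settings.register_profile(
    "default",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def chain_2x2() -> BipartiteNetwork:
    """The 4-node path: rows (2,1), cols (2,1), E=3."""
    return BipartiteNetwork(np.array([[1, 1], [1, 0]]))


@pytest.fixture
def anti_nested() -> BipartiteNetwork:
    """Two disjoint dyads: the least nested 2x2 arrangement."""
    return BipartiteNetwork(np.array([[1, 0], [0, 1]]))


@pytest.fixture
def random_net() -> BipartiteNetwork:
    rng = np.random.default_rng(42)
    return BipartiteNetwork((rng.random((15, 20)) < 0.3).astype(int))


def random_networks(count: int, n: int, m: int, fill: float, seed: int):
    rng = np.random.default_rng(seed)
    for _ in range(count):
        yield BipartiteNetwork((rng.random((n, m)) < fill).astype(int))
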