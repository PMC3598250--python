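import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_instance():
    """A small synthetic network + standardized expression, shared across tests."""
    import tigress

    net = tigress.generate_network(p=15, q=4, mean_out_degree=2, seed=7)
    X = tigress.simulate_expression(net, n=40, seed=8)
    return net, X
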