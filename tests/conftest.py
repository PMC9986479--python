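import numpy as np
import pytest

from sbmclust import ClusterSpec, generate_mixture


@pytest.fixture
def rng():
    return np.random.default_rng(20230220)


def random_mixture(rng, n_max=2000, n_dim=2, k_max=4, spread=8.0):
    """A random labelled Gaussian mixture for property tests."""
    k = int(rng.integers(1, k_max + 1))
    sizes = rng.multinomial(int(rng.integers(k * 10, n_max)), np.ones(k) / k)
    specs = [
        ClusterSpec.make(
            rng.uniform(-spread, spread, n_dim),
            max(1, int(s)),
            rng.uniform(0.3, 1.5),
        )
        for s in sizes
    ]
    return generate_mixture(specs, seed=int(rng.integers(2**31)))
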