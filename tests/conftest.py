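import numpy as np
import pytest

from rmstoch import ModelParams


@pytest.fixture
def baseline():
    """Baseline parameters m=1.5, c=0.4, e=1 used throughout."""
    return ModelParams(m=1.5, c=0.4, k=2.0, e=1.0, omega=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_interior_states(rng, n, low=0.05, high=8.0):
    """Log-uniform interior states spanning small and large densities."""
    return np.exp(rng.uniform(np.log(low), np.log(high), size=(n, 2)))
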