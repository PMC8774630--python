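import numpy as np
import pytest

from csde import Dictionary


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_gaussian_dict():
    """Five moderately overlapping Gaussian components."""
    return Dictionary.gaussian([0.0, 0.7, 1.5, 2.6, 4.0],
                               [1.0, 0.8, 0.6, 0.9, 1.3])


@pytest.fixture
def small_poisson_dict():
    return Dictionary.poisson([0.5, 1.0, 2.5, 4.0])
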