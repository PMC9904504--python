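import numpy as np
import pytest

from specais.io import TrialEnsemble
from specais.simulate import gen_ar1, gen_white_noise


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ar1_ensemble():
    """Stationary AR(1), phi=0.7, small multi-trial ensemble."""
    return gen_ar1(0.7, n_trials=5, n_samples=3000, seed=7)


@pytest.fixture
def noise_ensemble():
    return gen_white_noise(n_trials=5, n_samples=1200, seed=11)


@pytest.fixture
def tiny_ensemble():
    data = np.array([[0.0, 1.0, 0.0, 1.0], [1.0, 0.0, 1.0, 0.0]])
    return TrialEnsemble(data, fs=120.0, label="tiny")
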