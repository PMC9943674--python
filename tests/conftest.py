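import numpy as np
import pytest

from dragonet import PairedOmicsData, StudyConfig, generate_precision, sample_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_data(rng):
    """8 samples, 3 + 4 features of correlated Gaussian data."""
    base = rng.standard_normal((8, 1))
    X1 = 0.5 * base + rng.standard_normal((8, 3))
    X2 = 0.5 * base + rng.standard_normal((8, 4))
    return PairedOmicsData(X1=X1, X2=X2)


@pytest.fixture
def tiny_study():
    """Reduced two-layer design used to keep pipeline tests fast."""
    return StudyConfig(p1=20, p2=40, density=(0.05, 0.05, 0.02))


@pytest.fixture
def tiny_truth(tiny_study):
    return generate_precision(tiny_study, seed=7)


@pytest.fixture
def tiny_dataset(tiny_truth):
    return sample_dataset(tiny_truth, n=150, seed=8)
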