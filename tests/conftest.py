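import numpy as np
import pytest

from hksvm import CVConfig, KernelSpec, SyntheticConfig, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def positive_matrix(rng):
    """Strictly positive 8x12 matrix (microarray-like magnitudes)."""
    return rng.uniform(0.2, 50.0, size=(8, 12))


@pytest.fixture
def signed_matrix(rng):
    """Signed matrix with exact zeros sprinkled in."""
    X = rng.normal(0.0, 2.0, size=(7, 9))
    X[rng.random(X.shape) < 0.15] = 0.0
    return X


@pytest.fixture(scope="session")
def signal_dataset():
    """Separable fixture: strong multiplicative shift on 10/100 features."""
    return generate_synthetic(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def null_dataset():
    """Same recipe with effect=1 (no class signal)."""
    return generate_synthetic(SyntheticConfig(effect=1.0, seed=7))


@pytest.fixture
def fast_cv():
    return CVConfig(k=5, runs=3, seed=11)


@pytest.fixture
def hadamard_spec():
    return KernelSpec("hadamard", alpha=1.0)
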