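import numpy as np
import pytest

from bimmer import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated dataset shared by read-only tests."""
    config = simulate.SimulationConfig(
        M=5_000, n_normal=6, n_cancer=6,
        params=simulate.reference_params(alpha=0.2), seed=7,
    )
    return simulate.simulate_dataset(config)


def random_counts(rng, M, n_normal=2, n_cancer=2, K=3):
    """Unstructured random count matrices for oracle comparisons."""
    return (
        rng.integers(0, K + 1, size=(M, n_normal)),
        rng.integers(0, K + 1, size=(M, n_cancer)),
    )
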