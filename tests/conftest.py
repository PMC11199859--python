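import numpy as np
import pytest

from tffusion.benchmark import run_benchmark
from tffusion.data import generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_batch():
    """A small, easy (low-noise) labeled window batch for unit tests."""
    return generate_dataset(n_per_class=20, n_classes=3, n_channels=2,
                            window=64, noise_sd=0.1, seed=7)


@pytest.fixture(scope="session")
def benchmark_results():
    """The 3-seed synthetic benchmark over all augmentation modes.

    Session-scoped because it is the expensive part of the suite; the
    end-to-end recovery and ablation-direction checks both read it.
    """
    return run_benchmark([1, 2, 3])
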