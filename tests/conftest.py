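import numpy as np
import pytest

from moltox import FixtureSpec, generate_library, make_ssl_benchmark


@pytest.fixture(scope="session")
def library50():
    """50 unique synthetic molecules, ~20% carrying the nitro toxicophore."""
    return generate_library(50, seed=123, positive_fraction=0.2)


@pytest.fixture(scope="session")
def benchmark():
    """The default 60-labeled / 240-unlabeled SSL benchmark (seed 0)."""
    spec = FixtureSpec(n_labeled=60, n_unlabeled=240, label_noise=0.1,
                       imbalance_target=0.3, seed=0)
    return make_ssl_benchmark(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
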