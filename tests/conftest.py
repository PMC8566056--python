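import numpy as np
import pytest

from mselat import (
    MseParams,
    SyntheticConfig,
    entropy_matrix,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-size planted configuration for fast unit tests."""
    return SyntheticConfig(
        n_per_group=6,
        n_regions=12,
        n_timepoints=120,
        planted_regions=(1, 5, 9),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size planted dataset (20 x 90 x 246)."""
    return generate_dataset(SyntheticConfig(seed=5))


@pytest.fixture(scope="session")
def default_entropy(default_dataset):
    """Entropy matrix of the full-size dataset at (m=1, r=0.56, tau=3)."""
    return entropy_matrix(default_dataset, MseParams(m=1, r=0.56, tau=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
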