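import numpy as np
import pytest

from gliomatex import extract_feature_table, generate_texture_dataset


@pytest.fixture(scope="session")
def fixture_dataset():
    """The 4-class study set: 25 images/class, 128 px, seed 0."""
    return generate_texture_dataset(25, image_size=128, seed=0)


@pytest.fixture(scope="session")
def fixture_table(fixture_dataset):
    """Raw feature table of the study set (all six families)."""
    return extract_feature_table(fixture_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """Quick 2-image-per-class set for cheap behavioural checks."""
    return generate_texture_dataset(2, image_size=64, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
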