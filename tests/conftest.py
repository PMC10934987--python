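import numpy as np
import pytest

from hsiclass import (
    generate_cube,
    generate_signatures,
    make_centroid_svm,
    make_separating_forest,
    quadrant_layout,
)


@pytest.fixture(scope="session")
def signatures():
    """Small, well-separated signature set shared across tests."""
    return generate_signatures(n_classes=4, n_bands=12, seed=7)


@pytest.fixture(scope="session")
def small_scene(signatures):
    layout = quadrant_layout(10, 10, signatures.n_classes)
    return generate_cube(signatures, layout, noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def centroid_svm(signatures):
    return make_centroid_svm(signatures, gamma=10.0)


@pytest.fixture(scope="session")
def small_rf(signatures):
    return make_separating_forest(signatures, "rf", n_estimators=15, seed=1)


@pytest.fixture(scope="session")
def small_xgb(signatures):
    return make_separating_forest(signatures, "xgb", n_estimators=10, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
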