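import numpy as np
import pytest

from facevector import pipeline
from facevector.morphable import make_template


@pytest.fixture(scope="session")
def fx():
    """Miniature deterministic dataset: 12-vertex model, 8 faces, 4 raters."""
    return pipeline.fixture_suite(seed=0)


@pytest.fixture(scope="session")
def template():
    """Default desk-scale head template (146 vertices, 64x64 texture)."""
    return make_template(seed=7)


@pytest.fixture(scope="session")
def tiny_template():
    return make_template(
        n_lat=2, n_lon=5, texture_size=4, n_idio_shape=8, n_idio_texture=8, seed=3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
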