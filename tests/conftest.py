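import numpy as np
import pytest

from microquant import synth
from microquant.config import load_config


@pytest.fixture(scope="session")
def default_config():
    return load_config()


@pytest.fixture(scope="session")
def default_scene():
    """One default 20-cell scene, shared across tests (read-only)."""
    return synth.make_cell_scene(synth.SceneParams(seed=42))


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free default-geometry scene for exact-value checks."""
    return synth.make_cell_scene(synth.SceneParams(seed=42, noise="none"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def no_exclusion(shape):
    """Explicit empty exclusion mask (callers that know an image is cell-free)."""
    return np.zeros(shape, dtype=np.uint8)
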