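import numpy as np
import pytest

from jointscan.phantoms import PhantomParams, generate_dataset


@pytest.fixture(scope="session")
def small_params():
    """Phantom geometry small enough for fast whole-image pipelines."""
    return PhantomParams(image_w=256, image_h=224)


@pytest.fixture(scope="session")
def phantom_dataset(small_params):
    """Ten small phantoms (5 patients x 2 timepoints), fixed seed."""
    return generate_dataset(n_images=10, params=small_params, seed=42)


@pytest.fixture(scope="session")
def default_phantom():
    """One full-size (1005x835) phantom."""
    from jointscan.phantoms import generate_hand

    return generate_hand(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
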