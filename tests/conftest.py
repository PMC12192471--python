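import numpy as np
import pytest

from ctnps import (
    NoiseEnsemble,
    PhantomSpec,
    default_method_profiles,
    make_head_phantom,
)

PIXEL = 0.429  # mm, reconstruction grid of the emulated protocol


@pytest.fixture(scope="session")
def profiles():
    return default_method_profiles(1.0)


@pytest.fixture(scope="session")
def small_phantom():
    spec = PhantomSpec(matrix_size=64, n_slices=3)
    return make_head_phantom(spec)


@pytest.fixture(scope="session")
def white_noise_ensemble():
    """iid Gaussian noise, sigma = 10 HU, 5 reps, 50 slices of 128^2."""
    rng = np.random.default_rng(2024)
    imgs = rng.normal(0.0, 10.0, size=(5, 50, 128, 128))
    return NoiseEnsemble(imgs, PIXEL, provenance={"sigma": 10.0})
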