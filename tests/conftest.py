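import numpy as np
import pytest

from srh import (
    UnmixParams,
    default_phantom_spec,
    generate_phantom,
    make_default_library,
    unmix_cube,
)
from srh.phantom import default_axis


@pytest.fixture(scope="session")
def axis45():
    return default_axis()


@pytest.fixture(scope="session")
def library(axis45):
    return make_default_library(axis45)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(default_phantom_spec(noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(default_phantom_spec(noise_sd=0.02, seed=17))


@pytest.fixture(scope="session")
def noisy_full_maps(noisy_phantom, library):
    cube, _ = noisy_phantom
    return unmix_cube(cube, library, UnmixParams())


def random_mixture(rng, library, n_active=3, noise=0.0):
    """Random non-negative mixture spectrum from a library."""
    k = library.n_components
    c = np.zeros(k)
    idx = rng.choice(k, size=min(n_active, k), replace=False)
    c[idx] = rng.uniform(0.2, 2.0, size=idx.size)
    y = c @ library.spectra
    if noise:
        y = np.clip(y + rng.normal(0, noise, size=y.shape), 0, None)
    return y, c
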