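import numpy as np
import pytest

from omfwls.raster_io import MultispectralCube, RAW_ROLES
from omfwls.synthetic_scene import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240722)


@pytest.fixture
def small_cube(rng):
    """4-band 6x5 cube with positive reflectance-like values."""
    data = rng.uniform(0.01, 0.6, size=(4, 6, 5))
    return MultispectralCube(data, RAW_ROLES)


@pytest.fixture
def correlated_sample(rng):
    """8 x 10000 Gaussian sample with Toeplitz 0.5^|i-j| band correlation."""
    from scipy.linalg import cholesky, toeplitz

    C = toeplitz(0.5 ** np.arange(8))
    return cholesky(C, lower=True) @ rng.normal(size=(8, 10_000))


@pytest.fixture
def clean_scene():
    """Noise-free 128x128 scene: perfectly separable classes."""
    return generate_scene(SceneSpec(rows=128, cols=128, noise_sigma=0.0, seed=11))


@pytest.fixture
def noisy_scene():
    """Moderately noisy 128x128 scene with canopy gaps."""
    return generate_scene(
        SceneSpec(rows=128, cols=128, noise_sigma=0.05, gap_fraction=0.2, seed=11)
    )
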