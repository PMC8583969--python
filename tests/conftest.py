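import numpy as np
import pytest

from tdeconv import (
    ImageStack,
    NoiseModel,
    SimulationConfig,
    degrade,
    generate_clean_series,
    make_gaussian_psf,
)
from tdeconv.operators import apply_psf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_psf():
    return make_gaussian_psf(1.5, 7)


@pytest.fixture(scope="session")
def tiny_scene():
    """Small clean/noisy pair at medium noise for solver-level tests."""
    psf = make_gaussian_psf(1.5, 7)
    clean = generate_clean_series(
        SimulationConfig(canvas=(64, 64), frames=8, n_spots=12, seed=7)
    )
    blurred = apply_psf(clean, psf)
    drange = blurred.dynamic_range()
    noisy = degrade(
        clean,
        psf,
        NoiseModel(
            poisson_level=0.1 * float(blurred.data.max()),
            gaussian_variance=0.02 * drange**2,
            seed=11,
        ),
    )
    return {"clean": clean, "noisy": noisy, "psf": psf}


def random_stack(rng, shape=(3, 8, 8), loc=0.3, scale=0.4) -> ImageStack:
    return ImageStack(rng.normal(loc, scale, shape))
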