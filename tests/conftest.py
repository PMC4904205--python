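import numpy as np
import pytest

import lightresponse as lr


@pytest.fixture(scope="session")
def grid():
    return lr.DEFAULT_GRID


@pytest.fixture(scope="session")
def clean_rect_dataset(grid):
    """Noise-free rectangular-hyperbola curve with known truth."""
    m = lr.get_model("rectangular")
    truth = (0.06, 25.0, 1.5)
    ds = lr.LightResponseDataset("rect_clean", "1", grid, m.predict(truth, grid))
    return ds, truth


@pytest.fixture(scope="session")
def noisy_rect_dataset(grid):
    m = lr.get_model("rectangular")
    truth = (0.06, 25.0, 1.5)
    rng = np.random.default_rng(42)
    a_net = m.predict(truth, grid) + rng.normal(0.0, 0.3, grid.size)
    return lr.LightResponseDataset("rect_noisy", "1", grid, a_net), truth


@pytest.fixture(scope="session")
def zero_noise_suite():
    """Campaign-sized suite with exact (noise-free) observations."""
    return lr.generate_suite(42, seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_suite():
    """Campaign-sized suite under the default drawn noise levels."""
    return lr.generate_suite(42, seed=11)


@pytest.fixture(scope="session")
def zero_noise_de_fits(zero_noise_suite):
    """DE fit of each zero-noise curve with its generating model (cached:
    several acceptance properties read these)."""
    fits = []
    for i, c in enumerate(zero_noise_suite):
        fits.append(lr.fit(c.dataset, c.model, "de", seed=1000 + i))
    return fits
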