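import numpy as np
import pytest

from discslice.phantom import PhantomConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact default-contrast phantom study shared across tests."""
    return generate_study(PhantomConfig(n_patients=4, image_size=64, seed=0))


@pytest.fixture(scope="session")
def clean_study():
    """Misalignment-free, noise-free, bias-free study (degenerate config)."""
    return generate_study(PhantomConfig(
        n_patients=2, image_size=64, max_translation=0, max_rotation=0,
        max_scale_offset=0, noise_sd=0, bias_order=0, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blobs_4class():
    """Well-separated 4-class Gaussian blobs in 8 dimensions."""
    g = np.random.default_rng(7)
    X = np.vstack([g.normal(3 * i, 1.0, (15, 8)) for i in range(4)])
    y = np.repeat(["best_d3", "best_d4", "best_d5", "other_slices"], 15)
    return X, y
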