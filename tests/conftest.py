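import numpy as np
import pytest

from levelseg import (
    BilateralSpec,
    EvolveParams,
    GaussianSpec,
    GrayImage,
    add_gaussian_noise,
    edge_indicator_bilateral,
    edge_indicator_gaussian,
    evolve,
    init_binary_step,
    make_disk_image,
)

# canonical noisy-disk scene: 128x128, R=30 disk, 150-level contrast
FIXTURE_SHAPE = (128, 128)
FIXTURE_RADIUS = 30.0
FIXTURE_FG = 200.0
FIXTURE_BG = 50.0
FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def clean_disk():
    image, truth = make_disk_image(
        *FIXTURE_SHAPE,
        center=(FIXTURE_SHAPE[0] / 2.0, FIXTURE_SHAPE[1] / 2.0),
        radius=FIXTURE_RADIUS,
        fg=FIXTURE_FG,
        bg=FIXTURE_BG,
    )
    return image, truth


@pytest.fixture(scope="session")
def noisy_disk(clean_disk):
    image, truth = clean_disk
    return add_gaussian_noise(image, 10.0, FIXTURE_SEED), truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def seed_mask(shape=FIXTURE_SHAPE, margin=14):
    mask = np.zeros(shape, dtype=bool)
    mask[margin:-margin, margin:-margin] = True
    return mask


def run_fixture_evolution(noisy, variant, params=None):
    """Shared helper: smooth -> g -> evolve from the rectangle seed."""
    if variant == "gaussian":
        g = edge_indicator_gaussian(noisy, GaussianSpec(1.5))
    else:
        g = edge_indicator_bilateral(noisy, BilateralSpec(1.5, 75.0))
    phi0 = init_binary_step(noisy.shape, seed_mask(noisy.shape), 2.0)
    return evolve(phi0, g, params or EvolveParams())


@pytest.fixture(scope="session")
def evolved_gaussian(noisy_disk):
    noisy, _ = noisy_disk
    return run_fixture_evolution(noisy, "gaussian")


@pytest.fixture(scope="session")
def evolved_bilateral(noisy_disk):
    noisy, _ = noisy_disk
    return run_fixture_evolution(noisy, "bilateral")


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.uniform(0.0, 255.0, (32, 32)))
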