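import numpy as np
import pytest

from fdagseg import BankConfig, NoiseModel, piecewise_constant_scene
from fdagseg.kernels import directions_from_count


@pytest.fixture(scope="session")
def small_bank_config() -> BankConfig:
    """A cheap 3-scale, 4-direction bank for fast pipeline tests."""
    return BankConfig(
        scales=(1.0, 1.2, 1.5),
        directions=directions_from_count(4),
        control_scale=1.2,
    )


@pytest.fixture(scope="session")
def wide_scale_config() -> BankConfig:
    """Scale grid 0.8..1.8 used for characteristic-scale recovery."""
    return BankConfig(
        scales=tuple(round(0.8 + 0.1 * i, 1) for i in range(11)),
        directions=directions_from_count(8),
        control_scale=1.2,
    )


@pytest.fixture(scope="session")
def five_region_scene():
    """Seeded 128x128 scene with 5 regions, light blur and noise."""
    return piecewise_constant_scene(
        (128, 128), 5, blur_scale=1.0, noise=NoiseModel(epsilon0=0.02, seed=7), seed=7
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
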