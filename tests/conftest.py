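import numpy as np
import pytest

from rescuesim import (
    DEFAULT_CATEGORY_PARAMS,
    DonorProfile,
    GpdSupplyParams,
    RegionConfig,
    generate_donors,
)


@pytest.fixture
def grocers() -> GpdSupplyParams:
    return DEFAULT_CATEGORY_PARAMS["grocers"]


@pytest.fixture
def small_region() -> list[DonorProfile]:
    """A 30-donor synthetic region, small enough for fast day loops."""
    return generate_donors(RegionConfig(n_donors=30, n_towns=3, seed=7))


def make_donor(
    id: str = "d0",
    warehouse_km: float = 5.0,
    location: tuple[float, float] = (0.0, 0.0),
    rate: float = 1.0,
    scale: float = 100.0,
    shape: float = 0.0,
    category: str = "grocers",
) -> DonorProfile:
    return DonorProfile(
        id=id,
        category=category,
        square_feet=10_000.0,
        location=location,
        warehouse_km=warehouse_km,
        params=GpdSupplyParams(category, 0.0, rate, scale, shape),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
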