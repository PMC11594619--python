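import numpy as np
import pytest

from hostsdm.core_geo import GridSpec, Raster


@pytest.fixture
def small_spec() -> GridSpec:
    """A 20x25 grid at 2.5 arc-min, upper-left at (100E, 30N)."""
    return GridSpec(100.0, 30.0, 2.5 / 60.0, 20, 25)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def random_raster(small_spec, rng) -> Raster:
    vals = rng.normal(size=small_spec.shape)
    mask = np.zeros(small_spec.shape, dtype=bool)
    mask[0, 0] = True  # one nodata cell
    return Raster(small_spec, np.where(mask, np.nan, vals), mask, name="noise")


@pytest.fixture(scope="session")
def tiny_scenario():
    """A reduced landscape with the default species structure, shared
    across tests that only need a coherent world, not the full extent."""
    from hostsdm.synthetic_data import default_scenario

    spec = GridSpec(100.0, 30.0, 2.5 / 60.0, 60, 50)
    return default_scenario(seed=7, spec=spec, n_focal_presences=120, n_host_presences=80)
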