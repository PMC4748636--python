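import numpy as np
import pytest

from placmorph.synthetic import (
    FieldParams,
    simulate_field_all_stains,
)

# A mid-sized field reused by several measurement tests (simulated once).
DEFAULT_PARAMS = FieldParams(seed=7)

# A small, fast field for unit tests that re-simulate with tweaked knobs.
SMALL_PARAMS = FieldParams(
    seed=3,
    field_size_um=360.0,
    n_villi=8,
    villus_diameter_um_range=(35.0, 60.0),
    sna_per_mm2=180.0,  # dense aggregates so small fields still contain a few
)


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size field rendered in all five stain kinds, with truth."""
    images, truth = simulate_field_all_stains(DEFAULT_PARAMS)
    return images, truth


@pytest.fixture(scope="session")
def small_bundle():
    images, truth = simulate_field_all_stains(SMALL_PARAMS)
    return images, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
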