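import numpy as np
import pytest

from l3comp import PhantomSpec, classify, generate_phantom

# Compact phantom used throughout the unit tests: same shell structure as the
# default, scaled to a 192×192 raster so morphology stays fast.
SMALL_SPEC = PhantomSpec(
    rows=192,
    cols=192,
    spacing_mm=0.8,
    semi_axis_row_mm=50.0,
    semi_axis_col_mm=60.0,
    sat_ring_mm=12.0,
    muscle_wall_mm=8.0,
    fat_lining_mm=5.6,
    visceral_fat_fraction=0.45,
    vertebra_radius_mm=10.0,
    n_imat_pockets=6,
    imat_pocket_radius_mm=1.6,
    noise_sd_hu=0.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_case():
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_classified(small_case):
    return classify(small_case.ct)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
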