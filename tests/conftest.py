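import numpy as np
import pytest

from radsurv.deep import RandomConvBackbone
from radsurv.phantom import PhantomSpec, SurvivalGenConfig, generate_cohort

# a compact phantom keeps per-patient extraction cheap in the unit tests
SMALL_PHANTOM_KW = dict(
    grid_shape=(32, 32, 32),
    subregion_radii={"necrosis": 4.0, "enhancement": 7.0, "edema": 10.0},
)

# minimal phantom for survival-only experiments (image content irrelevant)
TINY_PHANTOM_KW = dict(
    grid_shape=(16, 16, 16),
    subregion_radii={"necrosis": 1.5, "enhancement": 2.5, "edema": 4.0},
)


def small_phantom(seed=0, **kw):
    return PhantomSpec(seed=seed, **{**SMALL_PHANTOM_KW, **kw})


def tiny_phantom(seed=0, **kw):
    return PhantomSpec(seed=seed, **{**TINY_PHANTOM_KW, **kw})


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient compact cohort for extraction-level tests."""
    return generate_cohort(6, small_phantom(seed=5), SurvivalGenConfig(seed=6))


@pytest.fixture(scope="session")
def one_patient(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def tiny_backbone():
    return RandomConvBackbone(seed=0, width=8)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
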