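import numpy as np
import pytest

from brightpath.synthetic_fixtures import (
    FixtureSpec,
    make_head_fixture,
    make_megapress,
    make_var_bold,
)


@pytest.fixture(scope="session")
def var_bold():
    """Default VAR-BOLD fixture with one planted causal voxel."""
    return make_var_bold(FixtureSpec(random_seed=7))


@pytest.fixture(scope="session")
def sphere_head():
    return make_head_fixture("sphere", radius=80.0, subdivisions=3)


@pytest.fixture(scope="session")
def ellipsoid_head():
    return make_head_fixture("ellipsoid", radius=(90.0, 75.0, 95.0), subdivisions=3)


@pytest.fixture(scope="session")
def clean_megapress():
    """320 interleaved jitter-free acquisitions at SNR 50."""
    return make_megapress(random_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
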