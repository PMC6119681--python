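import numpy as np
import pytest
from hypothesis import settings

from rntlq.microdosimetry import transport
from rntlq.synthetic import GroundTruth, gen_geometry_fixture

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_geometry():
    """200-cell packed monolayer in a reduced-radius well."""
    return gen_geometry_fixture(200, seed=3)


@pytest.fixture(scope="session")
def small_tally(small_geometry):
    """One reference transport run on the small fixture."""
    return transport(small_geometry, 20000, seed=4, store_tracks=True)


@pytest.fixture()
def ht29_truth():
    return GroundTruth(alpha=0.0842, beta=0.0239, cell_line="HT29")


@pytest.fixture()
def noiseless_truth():
    return GroundTruth(alpha=0.0842, beta=0.0239, od_sd_additive=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
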