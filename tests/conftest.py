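import numpy as np
import pytest

from nrplast.nrp import Searchlight
from nrplast.synthetic import ellipsoid_mask


@pytest.fixture(scope="session")
def default_mask():
    """Ellipsoidal test mask on the default 32^3 grid (~9300 voxels)."""
    return ellipsoid_mask()


@pytest.fixture(scope="session")
def default_searchlight(default_mask):
    """A 6 mm searchlight engine shared across tests (neighbor table is costly)."""
    return Searchlight(default_mask, radius_mm=6.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
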