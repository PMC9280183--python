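import numpy as np
import pytest

from eegfusion.montage import default_montage, project_aep
from eegfusion.topomap import grid_bounds_for


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def full_bounds(montage):
    return grid_bounds_for(project_aep(montage))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
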