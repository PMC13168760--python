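import numpy as np
import pytest

from pillarforce.beam import PillarGeometry


@pytest.fixture
def default_geometry() -> PillarGeometry:
    """Standard platform pillar: a=300 um, b=200 um, h=4 mm, E=2.414 MPa."""
    return PillarGeometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
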