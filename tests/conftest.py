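import numpy as np
import pytest

from drivestress.io_formats import Segment, SegmentMap
from drivestress.synthetic_data import make_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study():
    """One default synthetic drive, shared across read-only tests."""
    return make_study(seed=7)


@pytest.fixture
def segmap():
    """A small three-segment route starting at t=0."""
    return SegmentMap(
        segments=(
            Segment("City 1", "city", 0.0, 600.0),
            Segment("Highway 1", "highway", 600.0, 1320.0),
            Segment("Tollgate 1", "tollgate", 1320.0, 1380.0),
        )
    )
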