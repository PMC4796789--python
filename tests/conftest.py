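import numpy as np
import pytest

from cldend import CANONICAL_SPINE, build_cylinder


@pytest.fixture(scope="session")
def small_cylinder():
    """300 μm × 1 μm cylinder at 1 μm resolution."""
    return build_cylinder(300.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def canonical():
    return CANONICAL_SPINE


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
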