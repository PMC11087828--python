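import numpy as np
import pytest

from ctuq.ct_model import Geometry


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_geometry():
    return Geometry(n_angles=24, n_detectors=32, image_side=32)


@pytest.fixture(scope="session")
def desk_scale():
    """Problem sizes used by the slower end-to-end tests."""
    return {"side": 64, "detectors": 64}
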