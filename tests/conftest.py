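import numpy as np
import pytest

from blebmech.afm import CellGeometry


@pytest.fixture
def geometry():
    """A typical rounded melanoma cell: radius 10 um."""
    return CellGeometry(radius=10e-6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
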