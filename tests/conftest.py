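import numpy as np
import pytest

from camabund.detection import Camera, Grid


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def grid():
    return Grid()


@pytest.fixture
def north_camera():
    """Camera at the origin facing North (default viewshed geometry)."""
    return Camera(cell_id=0, x=0.0, y=0.0)
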