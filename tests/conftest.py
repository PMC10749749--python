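import numpy as np
import pytest

from mtfrc.stack import ImagePlane


def square_roi(x0: float, y0: float, x1: float, y1: float):
    """Axis-aligned rectangle polygon in (x, y) pixel coordinates."""
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_plane(rng):
    """64×64 white-noise plane, pixel size 0.1 µm."""
    return ImagePlane(rng.standard_normal((64, 64)), 0.1)
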