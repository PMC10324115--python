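import numpy as np
import pytest
from scipy import ndimage

from comflow import phantom
from comflow.wall_geometry import split_six, subdivide


@pytest.fixture(scope="session")
def small_phantom():
    """128x128 U phantom: 12 px wall, 32 px cavity, lightly smoothed."""
    return phantom.make_u_phantom(128, 128, 12, 32, smooth_sigma=1.0)


@pytest.fixture(scope="session")
def small_contour(small_phantom):
    return phantom.make_u_contour(small_phantom)


@pytest.fixture(scope="session")
def six_segments(small_contour):
    return split_six(small_contour)


@pytest.fixture(scope="session")
def twelve_segments(six_segments, small_contour):
    return subdivide(six_segments, small_contour)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def textured_image():
    """Smooth random texture in [0, 1] with structure at the 2-px scale."""
    g = np.random.default_rng(7).random((64, 64))
    t = ndimage.gaussian_filter(g, 2.0)
    return (t - t.min()) / (t.max() - t.min())
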