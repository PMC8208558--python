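import numpy as np
import pytest

from nepcount import SceneSpec, make_still


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def green_still():
    """One high-contrast synthetic still on the green background, with truth."""
    return make_still(SceneSpec(seed=1))


@pytest.fixture(scope="session")
def red_disk():
    """A 120-px-radius red disk on green with its analytic mask."""
    from skimage.draw import disk

    frame = np.zeros((480, 640, 3))
    frame[:] = (0.10, 0.45, 0.22)
    mask = np.zeros((480, 640), dtype=bool)
    rr, cc = disk((240, 320), 120)
    mask[rr, cc] = True
    frame[mask] = (0.65, 0.25, 0.20)
    return frame, mask
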