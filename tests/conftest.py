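import numpy as np
import pytest

from nemadef.synthetic import make_defect_director, make_scene

PIXEL_SIZE = 1.856  # um/px


@pytest.fixture(scope="session")
def pixel_size():
    return PIXEL_SIZE


@pytest.fixture(scope="session")
def comet_director():
    """Canonical +1/2 comet: core at the field center, tail along +x."""
    shape = (192, 192)
    cx = (shape[1] - 1) * PIXEL_SIZE / 2
    cy = (shape[0] - 1) * PIXEL_SIZE / 2
    d = make_defect_director([((cx, cy), 0.5, 0.0)], shape=shape, pixel_size=PIXEL_SIZE)
    return d, (cx, cy)


@pytest.fixture(scope="session")
def trefoil_director():
    """Canonical -1/2 trefoil: core at the center, axis along +x."""
    shape = (192, 192)
    cx = (shape[1] - 1) * PIXEL_SIZE / 2
    cy = (shape[0] - 1) * PIXEL_SIZE / 2
    d = make_defect_director([((cx, cy), -0.5, 0.0)], shape=shape, pixel_size=PIXEL_SIZE)
    return d, (cx, cy)


@pytest.fixture(scope="session")
def comet_scene():
    """Comet scene with rendered texture (session-cached: rendering is the
    slow part)."""
    shape = (192, 192)
    cx = (shape[1] - 1) * PIXEL_SIZE / 2
    cy = (shape[0] - 1) * PIXEL_SIZE / 2
    return make_scene([((cx, cy), 0.5, 0.0)], shape=shape, pixel_size=PIXEL_SIZE, seed=1)


def angdiff_deg(a, b):
    """Absolute difference of two full-circle angles, degrees."""
    return np.degrees(np.abs(np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))))
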