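import numpy as np
import pytest

from lnnb_flowscore import FlowField, synthetic


def crop_valid(flow: FlowField, margin: int) -> FlowField:
    """Restrict a flow field's validity mask to the interior.

    Oracle comparisons on periodically warped fixtures exclude a border of
    one filter half-width, where wrap-around content breaks the model.
    """
    v = flow.valid.copy()
    v[:margin, :] = v[-margin:, :] = False
    v[:, :margin] = v[:, -margin:] = False
    return FlowField(flow.vx, flow.vy, v, flow.frame_index)


@pytest.fixture(scope="session")
def texture_64():
    return synthetic.gen_texture(0, 64, 64)


@pytest.fixture(scope="session")
def translating_seq():
    """Small translating-texture fixture shared across flow tests."""
    return synthetic.gen_translating_sequence(
        1, (1.0, 0.0), h=96, w=128, t=15, frame_rate=30
    )


def grating(h, w, wavelength, theta, phase=0.0):
    """Sinusoidal grating used as an analytic filter-response oracle."""
    y, x = np.mgrid[0:h, 0:w].astype(float)
    k = 2 * np.pi / wavelength
    return 0.5 + 0.4 * np.cos(k * (x * np.cos(theta) + y * np.sin(theta)) + phase)
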