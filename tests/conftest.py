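import numpy as np
import pytest

from zfcardio import BeatParams, simulate_beating_ventricle


@pytest.fixture(scope="session")
def default_sim():
    """Noise-free default beating-ventricle simulation (6 cycles at 20 fps)."""
    params = BeatParams()
    stack, truth = simulate_beating_ventricle(params, n_frames=60)
    return params, stack, truth


@pytest.fixture()
def ellipse_mask():
    """Ideal axis-aligned elliptical mask, semi-axes 50/30 px at (64, 64)."""

    def make(a=50.0, b=30.0, center=(64, 64), shape=(129, 129), theta_deg=0.0):
        cy, cx = center[1], center[0]
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        t = np.deg2rad(theta_deg)
        u = (xx - cx) * np.cos(t) + (yy - cy) * np.sin(t)
        v = -(xx - cx) * np.sin(t) + (yy - cy) * np.cos(t)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    return make
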