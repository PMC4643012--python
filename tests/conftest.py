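import numpy as np
import pytest

from wavevar.numerics import SpaceTimeCube


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sinusoid_cube():
    """Traveling plane-wave movie: cos(k x - w t), period 20 frames."""
    nt, ny, nx = 80, 40, 40
    t = np.arange(nt)[:, None, None]
    x = np.arange(nx)[None, None, :]
    data = np.cos(2 * np.pi * (x / 10.0 - t / 20.0))
    return SpaceTimeCube(np.broadcast_to(data, (nt, ny, nx)).copy(), dt_record=1.0)


def spiral_phase_field(shape, x0, y0, sign=1):
    """Analytic phase field with one singularity at (x0, y0)."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    return sign * np.arctan2(yy - y0, xx - x0)
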