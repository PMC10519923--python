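import numpy as np
import pytest

from gbm4d.vst import StabilizedSinogram


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stabilized(rng):
    """A small smooth positive stabilized sinogram (3 frames, 1 slice, 32x32)."""
    yy, xx = np.mgrid[0:32, 0:32] / 32.0
    base = 10.0 + 5.0 * np.sin(2 * np.pi * yy) * np.cos(2 * np.pi * xx)
    data = np.stack([(0.8 + 0.1 * t) * base for t in range(3)])[:, None]
    return StabilizedSinogram(data, sigma=1.0)
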