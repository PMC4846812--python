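import numpy as np
import pytest

from batwake.core import SequenceMeta, VectorFieldFrame, make_grid


@pytest.fixture
def meta4():
    """Cruise-speed acquisition metadata (U = 4 m/s, 9 g animal)."""
    return SequenceMeta(U=4.0, mass=0.009)


@pytest.fixture
def small_grid():
    """A cheap 21 x 15 plane grid at the standard vector pitch."""
    return make_grid(width=0.048, height=0.0336, spacing=0.0024)


def make_frame(u, v, w, y=None, z=None, mask=None, t=0.0):
    """Frame constructor helper used across test modules."""
    u = np.asarray(u, dtype=float)
    if y is None:
        y = 0.0024 * np.arange(u.shape[0])
    if z is None:
        z = 0.0024 * np.arange(u.shape[1])
    if mask is None:
        mask = np.ones(u.shape, dtype=bool)
    return VectorFieldFrame(u=u, v=v, w=w, valid_mask=mask, timestamp=t, y=y, z=z)


@pytest.fixture
def frame_factory():
    return make_frame
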