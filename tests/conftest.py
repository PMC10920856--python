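import numpy as np
import pytest

from cme import BinaryMask


@pytest.fixture
def disk_mask():
    """Rasterized disk of radius 30 px centered in a 100x100 mask."""
    yy, xx = np.mgrid[0:100, 0:100]
    return BinaryMask((xx - 50) ** 2 + (yy - 50) ** 2 <= 30**2)


@pytest.fixture
def square_mask():
    """Centered filled 11x11 square in a 15x15 mask."""
    m = np.zeros((15, 15), dtype=bool)
    m[2:13, 2:13] = True
    return BinaryMask(m)


def rotation(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
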