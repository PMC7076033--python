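import math

import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from osteoorient.containers import IntensityImage, LabeledMask


def rasterized_ellipse(
    a: float,
    b: float,
    orientation_deg: float = 0.0,
    canvas: int = 160,
    label: int = 1,
) -> LabeledMask:
    """Single rasterized ellipse with half-axes a (major) and b (minor)."""
    m = np.zeros((canvas, canvas), dtype=np.int32)
    rr, cc = draw_ellipse(
        canvas / 2, canvas / 2, b, a, rotation=-math.radians(orientation_deg)
    )
    m[rr, cc] = label
    return LabeledMask(m)


@pytest.fixture
def disk_mask() -> LabeledMask:
    """Disk of radius 20 px, label 1."""
    return rasterized_ellipse(20, 20, canvas=64)


@pytest.fixture
def grating_60() -> IntensityImage:
    """Sinusoidal grating, wavevector at 60 deg, 20 cycles per side."""
    n = 256
    fx0, fy0 = 20 * math.cos(math.radians(60)), 20 * math.sin(math.radians(60))
    y, x = np.mgrid[0:n, 0:n]
    return IntensityImage(0.5 + 0.5 * np.cos(2 * np.pi * (fx0 * x + fy0 * y) / n))
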