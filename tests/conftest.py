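import numpy as np
import pytest

from patchdyn.geometry import CellGeometry
from patchdyn.simulate import SimConfig


@pytest.fixture
def geom():
    """Standard rod geometry: 3.0 x 0.89 um, 200 nm penetration depth."""
    return CellGeometry(length_um=3.0, diameter_um=0.89, penetration_depth_um=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_config():
    return SimConfig(seed=11)


def paint_rod(length_um=3.0, width_um=0.9, pixel_size_um=0.064, pad_px=8, angle_deg=0.0):
    """Binary spherocylinder mask painted directly onto a pixel grid."""
    import math

    r = width_um / 2
    half_cyl = (length_um - width_um) / 2
    n_rows = int(np.ceil(width_um / pixel_size_um)) + 2 * pad_px
    n_cols = int(np.ceil(length_um / pixel_size_um)) + 2 * pad_px
    n = max(n_rows, n_cols)
    yy, xx = np.mgrid[0:n, 0:n]
    cy, cx = (n - 1) / 2, (n - 1) / 2
    th = math.radians(angle_deg)
    xr = (xx - cx) * math.cos(th) + (yy - cy) * math.sin(th)
    yr = -(xx - cx) * math.sin(th) + (yy - cy) * math.cos(th)
    x_um = xr * pixel_size_um
    y_um = yr * pixel_size_um
    ax = np.clip(x_um, -half_cyl, half_cyl)
    return np.hypot(x_um - ax, y_um) <= r
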