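import numpy as np
import pytest

from endoprofile import phantom
from endoprofile.protocol import (
    functional_cine_protocol,
    permeability_vfa_protocol,
)


@pytest.fixture(scope="session")
def cine_protocol_small():
    """Functional cine protocol at a reduced matrix for fast unit tests."""
    return functional_cine_protocol().with_matrix((96, 96, 12))


@pytest.fixture(scope="session")
def vfa_protocol_small():
    """Permeability VFA protocol at a reduced matrix (same 8 angles, TR)."""
    return permeability_vfa_protocol().with_matrix((64, 56, 2))


@pytest.fixture(scope="session")
def tissue():
    return phantom.TissueParams.default()


@pytest.fixture(scope="session")
def geometry_small(cine_protocol_small):
    return phantom.bifurcating_geometry(cine_protocol_small)


def straight_tube_geometry(protocol, radius_mm=1.0, drift=(0.071, 0.043), **kwargs):
    """Unbranched straight (slightly tilted) cylinder along the slice axis.

    The small in-plane drift dithers the voxel grid so that per-slice
    pixel-count quantisation averages out, as in the main generator.
    """
    n = protocol.matrix[2]
    dz = protocol.slice_thickness_mm
    z = np.arange(n + 1) * dz
    row = 0.5 * protocol.fov_mm[0] + drift[0] * np.arange(n + 1)
    col = 0.5 * protocol.fov_mm[1] + drift[1] * np.arange(n + 1)
    defaults = dict(
        wall_thickness_mm=0.12,
        pulsation_amplitude=0.0,
        dilation_factor=1.0,
    )
    defaults.update(kwargs)
    return phantom.VesselGeometry(
        centerline_mm=np.column_stack([z, row, col]),
        radius_mm=np.full(n + 1, float(radius_mm)),
        **defaults,
    )
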