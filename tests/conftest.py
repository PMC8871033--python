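import numpy as np
import pytest

from septalflow.domain import VoxelMask
from septalflow.geometry import build_boundary_map, classify_nodes


@pytest.fixture(scope="session")
def closed_box_bmap():
    """10^3 box with solid walls all around: the conservation fixture."""
    fluid = np.zeros((10, 10, 10), dtype=bool)
    fluid[1:-1, 1:-1, 1:-1] = True
    return build_boundary_map(classify_nodes(VoxelMask(fluid)))


@pytest.fixture(scope="session")
def slab_bmap():
    """Plane channel (walls normal to z, periodic x/y) for wall-link tests."""
    from septalflow.phantom import make_channel
    return build_boundary_map(classify_nodes(make_channel(8, 8, 8)))
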