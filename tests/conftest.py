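import numpy as np
import pytest
from shapely.geometry import box

from frontiercar.graph import AreaGraph, build_adjacency


def grid_polygons(nrows, ncols):
    return [box(c, r, c + 1, r + 1) for r in range(nrows) for c in range(ncols)]


def grid_graph(nrows, ncols, rule="queen"):
    return build_adjacency(grid_polygons(nrows, ncols), rule=rule)


@pytest.fixture(scope="session")
def grid3x3_queen():
    return grid_graph(3, 3, "queen")


@pytest.fixture(scope="session")
def grid3x3_rook():
    return grid_graph(3, 3, "rook")


@pytest.fixture(scope="session")
def grid4x4_rook():
    return grid_graph(4, 4, "rook")


@pytest.fixture
def path_graph():
    """Path A-B-C as a pure edge-list graph."""
    return AreaGraph(unit_ids=("A", "B", "C"), edges=((0, 1), (1, 2)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
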