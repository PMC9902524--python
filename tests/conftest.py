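import warnings

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from walkcity.network import load_network
from walkcity.region_grid import RegionBoundary, build_square_grid
from walkcity.synthetic_city import CitySpec, generate_street_network, region_for


def make_network(node_xy, edge_pairs, lengths=None):
    """Build a StreetNetwork from explicit node coordinates and edge pairs."""
    nodes = pd.DataFrame(
        [{"node_id": i, "x": x, "y": y} for i, (x, y) in node_xy.items()]
    )
    edges = pd.DataFrame(
        [
            {
                "edge_id": k,
                "u": u,
                "v": v,
                "length_m": None if lengths is None else lengths[k],
            }
            for k, (u, v) in enumerate(edge_pairs)
        ]
    )
    return load_network(nodes, edges)


@pytest.fixture
def lattice_spec():
    return CitySpec(seed=1, layout="grid", extent_m=1000.0, block_m=250.0, pop_total=1600)


@pytest.fixture
def lattice_net(lattice_spec):
    return generate_street_network(lattice_spec)


@pytest.fixture
def lattice_region(lattice_spec):
    return region_for(lattice_spec)


@pytest.fixture
def lattice_grid(lattice_spec, lattice_region):
    grid = build_square_grid(lattice_region)
    grid["population"] = 100.0
    return grid


@pytest.fixture
def path_net():
    """A straight path of four 300 m edges: 0 -300- 1 -300- 2 -300- 3 -300- 4."""
    xy = {i: (300.0 * i, 0.0) for i in range(5)}
    return make_network(xy, [(0, 1), (1, 2), (2, 3), (3, 4)])
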