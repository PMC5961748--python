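import warnings

import numpy as np
import pytest

from vaspol.fixtures import (
    PlexusSpec,
    locate_vav_boundary_nodes,
    make_tube_mask,
    make_vav_plexus,
)
from vaspol.flow import BoundaryCondition, RheologyModel, solve_flow
from vaspol.reconstruct import (
    VesselEdge,
    VesselNetwork,
    VesselNode,
    build_network,
)


@pytest.fixture(scope="session")
def tube_mask():
    return make_tube_mask(21, 200, "horizontal")


@pytest.fixture(scope="session")
def tube_network(tube_mask):
    return build_network(tube_mask)


def make_single_tube(radius_um=10.0, length_um=100.0):
    """Hand-built one-edge network with exact radius/length (no raster)."""
    path = np.array([[0.0, 0.0], [length_um, 0.0]])
    return VesselNetwork(
        nodes={0: VesselNode(0, 0.0, 0.0), 1: VesselNode(1, length_um, 0.0)},
        edges={0: VesselEdge(0, 0, 1, path, length_um, radius_um)},
        pixel_size=1.0,
    )


@pytest.fixture
def single_tube():
    return make_single_tube()


@pytest.fixture
def tube_bcs():
    return [
        BoundaryCondition(node=0, pressure=10.0, role="inlet"),
        BoundaryCondition(node=1, pressure=0.0, role="outlet"),
    ]


@pytest.fixture
def newtonian_blood():
    return RheologyModel(kind="newtonian", mu=3.5e-3)


@pytest.fixture(scope="session")
def vav():
    """Built + solved V-A-V plexus (Carreau-Yasuda), shared across tests."""
    mask, bc_spec = make_vav_plexus()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_network(mask)
    bcs = locate_vav_boundary_nodes(net, bc_spec)
    sol = solve_flow(net, bcs, RheologyModel(kind="carreau_yasuda"))
    return mask, net, bcs, sol
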