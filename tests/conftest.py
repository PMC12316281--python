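"""Shared fixtures: tiny hand-built networks and a small synthetic city.

Everything is generated at test time; no data files ship with the suite.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from foodexposure import (
    CityConfig,
    generate_households,
    generate_network,
    generate_outlets,
)
from foodexposure.network import StreetNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def single_edge_net() -> StreetNetwork:
    """One straight 2000 m edge."""
    return StreetNetwork.from_edges({0: (0, 0), 1: (2000, 0)}, [(0, 1)])


@pytest.fixture(scope="session")
def star_net() -> StreetNetwork:
    """Four 300 m spokes meeting at the origin."""
    nodes = {0: (0, 0), 1: (300, 0), 2: (-300, 0), 3: (0, 300), 4: (0, -300)}
    return StreetNetwork.from_edges(nodes, [(0, 1), (0, 2), (0, 3), (0, 4)])


@pytest.fixture(scope="session")
def triangle_net() -> StreetNetwork:
    """3-4-5 right triangle."""
    return StreetNetwork.from_edges(
        {0: (0, 0), 1: (3, 0), 2: (3, 4)}, [(0, 1), (1, 2), (0, 2)]
    )


@pytest.fixture(scope="session")
def small_city() -> CityConfig:
    """A compact city: 13x13 grid, moderate outlet density, 80 households."""
    return CityConfig(
        seed=11,
        grid_extent_m=1500.0,
        node_spacing_m=250.0,
        zone_radii_m=(500.0, 1000.0),
        outlet_intensity0=60.0,
        decay_scale_m=750.0,
        n_households=80,
    )


@pytest.fixture(scope="session")
def small_city_layers(small_city):
    net = generate_network(small_city)
    outlets = generate_outlets(small_city, net)
    households = generate_households(small_city, net)
    return net, outlets, households


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
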