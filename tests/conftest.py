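"""Shared fixtures: small analytic geometries and one default synthetic scenario."""

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Polygon

from speleosdm import cave_geometry as cg
from speleosdm import synthetic_data as sd


@pytest.fixture(scope="session")
def corridor_level():
    """Straight 100 m x 2 m east-west corridor with an axial centerline."""
    poly = Polygon([(0, 0), (100, 0), (100, 2), (0, 2)])
    g = nx.Graph()
    g.add_node("a", pos=(1.0, 1.0))
    g.add_node("b", pos=(99.0, 1.0))
    g.add_edge("a", "b", length=98.0)
    return cg.LevelGeometry(1, poly, g)


@pytest.fixture(scope="session")
def corridor_grid(corridor_level):
    return cg.rasterize_boundary(corridor_level, cell_size_m=0.5)


@pytest.fixture(scope="session")
def square_level():
    """10 m x 10 m axis-aligned square boundary."""
    poly = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
    return cg.LevelGeometry(1, poly, nx.Graph())


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic scenario (seed 1), shared across tests."""
    return sd.build_truth_bundle(sd.ScenarioConfig(seed=1))
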