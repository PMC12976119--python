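"""Shared fixtures: hand-built toy stream networks and alignment helpers.

The toy networks are laid out on vertical lines so that along-channel
distances equal coordinate differences and every expected slope can be
(and was) computed by hand; the expectations live next to the fixtures.
"""

import networkx as nx
import numpy as np
import pytest

from ampexp.popgen_core import HaplotypeAlignment
from ampexp.stream_geometry import SiteRecord, StreamNetwork


def build_network(nodes, edges):
    """nodes: {id: (x, y, elev)}; edges: [(u, v, [geometry])]."""
    g = nx.DiGraph()
    for nid, (x, y, z) in nodes.items():
        g.add_node(nid, x=x, y=y, elevation=z)
    for edge in edges:
        u, v = edge[0], edge[1]
        geom = edge[2] if len(edge) > 2 else None
        if geom is None:
            geom = [
                (nodes[u][0], nodes[u][1], nodes[u][2]),
                (nodes[v][0], nodes[v][1], nodes[v][2]),
            ]
        g.add_edge(u, v, geometry=geom)
    return StreamNetwork(g)


@pytest.fixture
def toy_symmetric():
    """Straight 250 m channel, uniform 10% gradient.

    Site 100 m below the top: end points 100 m up (z=110) and down
    (z=90), site z=100 -> both slopes 10%, result 10.0.
    """
    net = build_network(
        {0: (0, 250, 110.0), 1: (0, 0, 85.0)},
        [(0, 1)],
    )
    site = SiteRecord(site_id=0, edge=(0, 1), dist_along=100.0)
    return net, site, 10.0


@pytest.fixture
def toy_lower_of_two():
    """Kinked elevation profile: 10% above the site, 1% below -> 1.0.

    Geometry breakpoints: z=110 at the upstream end point (100 m above),
    z=100 at the site, z=99 at the downstream end point (100 m below).
    """
    geom = [(0, 250, 110.0), (0, 150, 100.0), (0, 50, 99.0), (0, 0, 98.5)]
    net = build_network(
        {0: (0, 250, 110.0), 1: (0, 0, 98.5)},
        [(0, 1, geom)],
    )
    site = SiteRecord(site_id=0, edge=(0, 1), dist_along=100.0)
    return net, site, 1.0


@pytest.fixture
def toy_double_confluence():
    """Confluences 40 m up and 60 m down of the site; both sides obstructed.

    End points fall on the branching nodes at their true distances:
    upstream node z=105, site z=103 (2 m over 40 m -> 5%); downstream
    node z=102.4 (0.6 m over 60 m -> 1%).  Lower slope -> 1.0.
    """
    nodes = {
        10: (-50, 150, 106.0),   # tributary sources into the upper confluence
        11: (50, 150, 106.5),
        0: (0, 100, 105.0),      # upper confluence (in-degree 2)
        12: (60, 30, 103.5),     # tributary into the lower confluence
        1: (0, 0, 102.4),        # lower confluence (in-degree 2)
        2: (0, -80, 102.0),      # downstream continuation
    }
    main_geom = [(0, 100, 105.0), (0, 60, 103.0), (0, 0, 102.4)]
    net = build_network(
        nodes,
        [(10, 0), (11, 0), (0, 1, main_geom), (12, 1), (1, 2)],
    )
    site = SiteRecord(site_id=0, edge=(0, 1), dist_along=40.0)
    return net, site, 1.0


@pytest.fixture
def toy_spring():
    """Site 50 m below a source: downstream end point only (3% -> 3.0)."""
    geom = [(0, 150, 101.0), (0, 100, 100.0), (0, 0, 97.0)]
    net = build_network(
        {0: (0, 150, 101.0), 1: (0, 0, 97.0)},
        [(0, 1, geom)],
    )
    site = SiteRecord(site_id=0, edge=(0, 1), dist_along=50.0)
    return net, site, 3.0


@pytest.fixture
def toy_single_confluence():
    """Confluence 40 m upstream, downstream clean: upstream side dropped.

    Downstream end point 100 m below the site: z drops 101 -> 99 -> 2%.
    (Upstream side would have been 5%.)
    """
    nodes = {
        10: (-50, 260, 104.0),
        11: (50, 260, 104.5),
        0: (0, 200, 103.0),      # confluence (in-degree 2)
        1: (0, 0, 98.8),
    }
    geom = [(0, 200, 103.0), (0, 160, 101.0), (0, 60, 99.0), (0, 0, 98.8)]
    net = build_network(nodes, [(10, 0), (11, 0), (0, 1, geom)])
    site = SiteRecord(site_id=0, edge=(0, 1), dist_along=40.0)
    return net, site, 2.0


def random_alignment(rng, n, length, alphabet=b"ACGT", p_missing=0.0):
    """Random (unstructured) alignment for oracle-equivalence tests."""
    chars = np.frombuffer(alphabet, dtype="S1")
    mat = chars[rng.integers(0, len(chars), size=(n, length))]
    if p_missing > 0:
        mask = rng.random((n, length)) < p_missing
        mat[mask] = b"N"
    return HaplotypeAlignment([f"s{i}" for i in range(n)], mat)
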