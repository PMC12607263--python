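"""Independent reference computations used by the tests.

The backbone oracle enumerates *all* simple paths between an edge's
endpoints (with the edge removed) and compares the best p-norm path length
against the edge weight — no shortest-path machinery shared with the
implementation under test.
"""

import math

import networkx as nx
import numpy as np


def brute_force_backbone(g: nx.Graph, p: float):
    """(kept, removed) edge sets by exhaustive simple-path enumeration."""
    kept, removed = set(), set()
    for u, v, data in g.edges(data=True):
        w = data["weight"]
        h = g.copy()
        h.remove_edge(u, v)
        bypass = False
        for path in nx.all_simple_paths(h, u, v):
            weights = [h[a][b]["weight"] for a, b in zip(path, path[1:])]
            if math.isinf(p):
                plen, target = max(weights), w
            else:
                plen, target = sum(x ** p for x in weights), w ** p
            if plen < target:
                bypass = True
                break
        (removed if bypass else kept).add(tuple(sorted((u, v))))
    return kept, removed


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 8) -> nx.Graph:
    """A connected weighted graph with 3..max_nodes nodes."""
    while True:
        n = int(rng.integers(3, max_nodes + 1))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    g.add_edge(i, j, weight=float(rng.uniform(0.5, 10.0)))
        if g.number_of_edges() and nx.is_connected(g):
            return g


def two_sphere_exposed_area(r: float, probe: float, d: float) -> float:
    """Analytic exposed area of one of two equal spheres of expanded
    radius R = r + probe whose centers are d apart: the full sphere minus
    the spherical cap buried inside the neighbor, 2*pi*R*h with
    h = R - d/2."""
    R = r + probe
    h = R - d / 2.0
    return 4.0 * math.pi * R * R - 2.0 * math.pi * R * h
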