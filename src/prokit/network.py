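"""Residue distance networks, backbone sparsification, and region graphs.

A distance network places one node per (polymer) residue and weights each
edge by the inter-residue distance in Angstroms, either the minimum over
heavy-atom pairs (``closest_atom``, the usual contact-map convention) or
the C-alpha separation (``c_alpha``).  Only pairs within a cutoff become
edges; isolated residues stay in the node set.

Sparsification comes in two flavours.  Thresholding simply drops edges
longer than a new, smaller cutoff.  The distance-backbone family instead
removes an edge of weight d exactly when some indirect path between its
endpoints is shorter than d under a p-norm path length

    len_p(path) = (sum_i d_i^p)^(1/p),      len_inf(path) = max_i d_i.

p = 1 gives the metric backbone, p = 2 the Euclidean backbone, p = inf the
ultrametric backbone.  Because every path through an edge is at least as
long as that edge under any p-norm, the removal test reduces to comparing
each edge weight with the all-pairs shortest p-length, computed by Dijkstra
on weights raised to the p-th power (finite p) or by minimax distances on a
minimum spanning tree (p = inf).  Backbone removal can never disconnect a
component: the shortest-path tree edges themselves are never bypassed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree
from scipy.spatial import cKDTree

from .annotation import ResidueAnnotationTable, SiteAnnotation
from .structure import ResidueKey, Structure

__all__ = [
    "DistanceNetwork",
    "BackboneResult",
    "RegionGraph",
    "distance_network",
    "contact_map",
    "threshold_sparsify",
    "generalized_backbone",
    "euclidean_backbone",
    "metric_backbone",
    "ultrametric_backbone",
    "region_distance_graph",
    "export_edgelist",
    "read_edgelist",
    "adjacency_matrix",
]

logger = logging.getLogger(__name__)

Edge = tuple[ResidueKey, ResidueKey]

#: Annotation kinds selectable for region graphs -> feature_type column.
REGION_KINDS: dict[str, str] = {
    "region": "region",
    "binding_site": "binding",
    "active_site": "active_site",
    "ptm_site": "ptm",
}


def _canonical(u, v) -> tuple:
    return (u, v) if u <= v else (v, u)


@dataclass
class DistanceNetwork:
    """Weighted undirected residue graph; weights are distances in A."""

    graph: nx.Graph
    cutoff: float
    metric_mode: str = "closest_atom"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[ResidueKey, ResidueKey, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


@dataclass
class BackboneResult:
    """Partition of a network's edges into backbone and semi-metric sets."""

    network: DistanceNetwork
    kept_edges: set[Edge]
    removed_edges: set[Edge]
    p: float

    @property
    def n_kept(self) -> int:
        return len(self.kept_edges)

    @property
    def n_removed(self) -> int:
        return len(self.removed_edges)

    def kept_network(self) -> DistanceNetwork:
        """The backbone as a network (same nodes, kept edges only)."""
        g = nx.Graph()
        g.add_nodes_from(self.network.graph.nodes)
        for u, v in self.kept_edges:
            g.add_edge(u, v, weight=self.network.graph[u][v]["weight"])
        return DistanceNetwork(g, self.network.cutoff, self.network.metric_mode)


@dataclass
class RegionGraph:
    """Graph over annotated regions/sites; weights are minimum
    inter-residue distances between the residue sets (0 when they share a
    residue)."""

    graph: nx.Graph
    max_distance: float = math.inf
    dropped: list[str] = field(default_factory=list)


def _residue_atom_coords(structure: Structure, metric_mode: str):
    """Per-residue heavy-atom (or CA) coordinate arrays, skipping HETATMs."""
    keys: list[ResidueKey] = []
    coord_sets: list[np.ndarray] = []
    for res in structure.polymer_residues():
        if metric_mode == "c_alpha":
            ca = res.atom("CA")
            if ca is None:
                warnings.warn(
                    f"residue {res.key.label} has no CA atom; skipped in "
                    "c_alpha mode", stacklevel=3,
                )
                continue
            coords = ca.coords[None, :]
        else:
            heavy = res.heavy_atoms()
            if not heavy:
                continue
            coords = np.array([a.coords for a in heavy])
        keys.append(res.key)
        coord_sets.append(coords)
    return keys, coord_sets


def distance_network(structure: Structure, cutoff: float,
                     metric_mode: str = "closest_atom",
                     min_separation: int = 0) -> DistanceNetwork:
    """Build the residue distance network at a distance cutoff.

    An edge joins residues i and j when their distance (per
    ``metric_mode``) is <= ``cutoff`` (closed boundary).  Hydrogens and
    HETATM residues never participate, so the result is identical for
    protonated and unprotonated inputs.  ``min_separation`` > 0 drops
    same-chain pairs closer than that many sequence positions.
    """
    if cutoff <= 0 or math.isnan(cutoff):
        raise ValueError("cutoff must be positive")
    if metric_mode not in ("closest_atom", "c_alpha"):
        raise ValueError(f"unknown metric_mode {metric_mode!r}")
    if len(structure) == 0:
        raise ValueError("structure has no residues")

    keys, coord_sets = _residue_atom_coords(structure, metric_mode)
    g = nx.Graph()
    g.add_nodes_from(keys)
    if not keys:
        return DistanceNetwork(g, cutoff, metric_mode)

    flat = np.concatenate(coord_sets)
    owner = np.concatenate([
        np.full(len(c), i) for i, c in enumerate(coord_sets)
    ])
    tree = cKDTree(flat)
    best: dict[tuple[int, int], float] = {}
    for a, b in tree.query_pairs(cutoff):
        ri, rj = int(owner[a]), int(owner[b])
        if ri == rj:
            continue
        pair = (ri, rj) if ri < rj else (rj, ri)
        d = float(np.linalg.norm(flat[a] - flat[b]))
        if d < best.get(pair, math.inf):
            best[pair] = d

    for (ri, rj), d in best.items():
        ki, kj = keys[ri], keys[rj]
        if (min_separation > 0 and ki.chain_id == kj.chain_id
                and abs(ki.seq_number - kj.seq_number) <= min_separation):
            continue
        if d <= cutoff:
            g.add_edge(ki, kj, weight=d)
    return DistanceNetwork(g, cutoff, metric_mode)


def contact_map(structure: Structure, cutoff: float = 7.0,
                metric_mode: str = "closest_atom",
                min_separation: int = 0) -> DistanceNetwork:
    """Residue contact map: a distance network at contact scale.

    Identical edge-for-edge to :func:`distance_network`; cutoffs outside
    the customary 6-12 A contact range are accepted with an informational
    log message.
    """
    if not 6.0 <= cutoff <= 12.0:
        logger.info(
            "contact-map cutoff %.2f A is outside the customary 6-12 A range",
            cutoff,
        )
    return distance_network(structure, cutoff, metric_mode, min_separation)


def threshold_sparsify(network: DistanceNetwork,
                       new_cutoff: float) -> DistanceNetwork:
    """Drop edges longer than ``new_cutoff`` (which must not exceed the
    network's cutoff — thresholding can only remove edges).  Nodes are
    preserved."""
    if new_cutoff < 0 or math.isnan(new_cutoff):
        raise ValueError("new_cutoff must be non-negative")
    if new_cutoff > network.cutoff:
        raise ValueError(
            f"new cutoff {new_cutoff} exceeds network cutoff {network.cutoff}; "
            "thresholding cannot add edges"
        )
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    for u, v, d in network.graph.edges(data=True):
        if d["weight"] <= new_cutoff:
            g.add_edge(u, v, weight=d["weight"])
    return DistanceNetwork(g, new_cutoff, network.metric_mode)


def _pairwise_p_lengths(g: nx.Graph, nodes: list, p: float) -> np.ndarray:
    """All-pairs shortest p-norm path lengths, returned as len_p^p for
    finite p (so they compare directly with w^p) or the minimax distance
    for p = inf."""
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for u, v, d in g.edges(data=True):
        w = d["weight"] ** p if math.isfinite(p) else d["weight"]
        rows.append(idx[u]); cols.append(idx[v]); vals.append(w)
        rows.append(idx[v]); cols.append(idx[u]); vals.append(w)
    mat = csr_array((vals, (rows, cols)), shape=(n, n))
    if math.isfinite(p):
        return dijkstra(mat, directed=False)
    # p = inf: minimax path distance = max edge on the minimum-spanning-
    # forest path (classic bottleneck shortest-path result)
    mst = minimum_spanning_tree(mat)
    forest = nx.Graph()
    forest.add_nodes_from(range(n))
    coo = mst.tocoo()
    for i, j, w in zip(coo.row, coo.col, coo.data):
        forest.add_edge(int(i), int(j), weight=float(w))
    out = np.full((n, n), np.inf)
    np.fill_diagonal(out, 0.0)
    for src in range(n):
        # DFS over the forest carrying the running max edge weight
        stack = [(src, 0.0)]
        seen = {src}
        while stack:
            node, running = stack.pop()
            for nbr, data in forest[node].items():
                if nbr not in seen:
                    seen.add(nbr)
                    m = max(running, data["weight"])
                    out[src, nbr] = m
                    stack.append((nbr, m))
    return out


def generalized_backbone(network: DistanceNetwork, p: float) -> BackboneResult:
    """Distance backbone under the p-norm path-length composition.

    An edge (u, v) of weight d is *semi-metric* (removed) iff some path
    between u and v avoiding the edge has p-length strictly less than d;
    ties keep the edge.  Requires p >= 1 (or ``math.inf``), where the
    composition is monotone and the Dijkstra relaxation is valid.
    """
    if not (p >= 1):  # also rejects NaN
        raise ValueError("p must be >= 1 (or math.inf)")
    nodes = list(network.graph.nodes)
    kept: set[Edge] = set()
    removed: set[Edge] = set()
    if network.graph.number_of_edges() == 0:
        return BackboneResult(network, kept, removed, p)
    dist = _pairwise_p_lengths(network.graph, nodes, p)
    idx = {u: i for i, u in enumerate(nodes)}
    for u, v, d in network.graph.edges(data=True):
        w = d["weight"] ** p if math.isfinite(p) else d["weight"]
        # any path through (u,v) is >= w under the p-norm, so a strictly
        # smaller shortest length certifies a bypass that avoids the edge
        if dist[idx[u], idx[v]] < w:
            removed.add(_canonical(u, v))
        else:
            kept.add(_canonical(u, v))
    return BackboneResult(network, kept, removed, p)


def euclidean_backbone(network: DistanceNetwork) -> BackboneResult:
    """Euclidean (p = 2) distance backbone."""
    return generalized_backbone(network, 2.0)


def metric_backbone(network: DistanceNetwork) -> BackboneResult:
    """Metric (p = 1) distance backbone."""
    return generalized_backbone(network, 1.0)


def ultrametric_backbone(network: DistanceNetwork) -> BackboneResult:
    """Ultrametric (p = inf) distance backbone."""
    return generalized_backbone(network, math.inf)


@dataclass(frozen=True)
class RegionNode:
    label: str
    kind: str
    residues: frozenset

    def __repr__(self) -> str:  # noqa: D105
        return self.label

    def __lt__(self, other: "RegionNode") -> bool:
        return self.label < other.label

    @property
    def size(self) -> int:
        return len(self.residues)


def region_distance_graph(structure: Structure,
                          table: ResidueAnnotationTable,
                          kinds: tuple[str, ...] = tuple(REGION_KINDS),
                          max_distance: float = math.inf) -> RegionGraph:
    """Graph whose nodes are annotated regions/sites and whose edge weights
    are the minimum heavy-atom distances between their residue sets.

    One node per selected annotation (single sites become 1-residue
    nodes).  Annotations with no structurally resolved residue are dropped
    with a warning; overlapping regions get weight 0; edges longer than
    ``max_distance`` are omitted.
    """
    unknown = [k for k in kinds if k not in REGION_KINDS]
    if unknown:
        raise ValueError(f"unknown region kinds {unknown!r}; "
                         f"choose from {sorted(REGION_KINDS)}")
    by_seq: dict[int, list] = {}
    for res in structure.polymer_residues():
        by_seq.setdefault(res.seq_number, []).append(res)

    nodes: list[RegionNode] = []
    coords: list[np.ndarray] = []
    dropped: list[str] = []
    labels_seen: dict[str, int] = {}
    for kind in kinds:
        for ann in table.annotations_of(REGION_KINDS[kind]):
            residues = [res for pos in range(ann.start, ann.end + 1)
                        for res in by_seq.get(pos, [])]
            if not residues:
                dropped.append(ann.label)
                continue
            atom_coords = np.array([a.coords for res in residues
                                    for a in res.heavy_atoms()])
            label = f"{kind}:{ann.start}" if ann.start == ann.end \
                else f"{kind}:{ann.start}-{ann.end}"
            if label in labels_seen:
                labels_seen[label] += 1
                label = f"{label}#{labels_seen[label]}"
            else:
                labels_seen[label] = 1
            nodes.append(RegionNode(label, kind,
                                    frozenset(r.key for r in residues)))
            coords.append(atom_coords)
    if dropped:
        warnings.warn(
            "annotations with no structurally resolved residues dropped: "
            + ", ".join(dropped), stacklevel=2,
        )

    g = nx.Graph()
    g.add_nodes_from(nodes)
    trees = [cKDTree(c) for c in coords]
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if nodes[i].residues & nodes[j].residues:
                weight = 0.0
            else:
                d, _ = trees[j].query(coords[i])
                weight = float(np.min(d))
            if weight <= max_distance:
                g.add_edge(nodes[i], nodes[j], weight=weight)
    return RegionGraph(graph=g, max_distance=max_distance, dropped=dropped)


def _node_label(node) -> str:
    if isinstance(node, ResidueKey):
        return node.label
    if isinstance(node, RegionNode):
        return node.label
    return str(node)


def export_edgelist(obj: DistanceNetwork | RegionGraph | BackboneResult
                    ) -> pd.DataFrame:
    """Tabular edge list: columns u, v, weight (4 decimals) and, for
    backbone results, a kept flag in {0, 1}.  Rows are sorted by (u, v)."""
    if isinstance(obj, BackboneResult):
        g = obj.network.graph
        rows = [
            (_node_label(u), _node_label(v), round(d["weight"], 4),
             int(_canonical(u, v) in obj.kept_edges))
            for u, v, d in g.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["u", "v", "weight", "kept"])
    else:
        g = obj.graph
        rows = [
            (_node_label(u), _node_label(v), round(d["weight"], 4))
            for u, v, d in g.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["u", "v", "weight"])
    return df.sort_values(["u", "v"], kind="stable").reset_index(drop=True)


def read_edgelist(df: pd.DataFrame) -> set[tuple[str, str]]:
    """Edge set from an exported edge list (labels as written)."""
    return {tuple(sorted((str(r.u), str(r.v)))) for r in df.itertuples()}


def adjacency_matrix(network: DistanceNetwork) -> pd.DataFrame:
    """Dense residues x residues distance matrix; 0 marks absent edges."""
    labels = [_node_label(n) for n in network.graph.nodes]
    mat = nx.to_numpy_array(network.graph, weight="weight")
    return pd.DataFrame(mat, index=labels, columns=labels)
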