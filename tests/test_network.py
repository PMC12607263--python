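import math

import networkx as nx
import numpy as np
import pytest

from oracles import brute_force_backbone, random_connected_graph
from prokit import fixtures
from prokit.annotation import SiteAnnotation, project_to_residues
from prokit.network import (
    DistanceNetwork,
    adjacency_matrix,
    contact_map,
    distance_network,
    euclidean_backbone,
    export_edgelist,
    generalized_backbone,
    read_edgelist,
    region_distance_graph,
    threshold_sparsify,
)


def _network_from(g: nx.Graph) -> DistanceNetwork:
    cutoff = max((d["weight"] for _, _, d in g.edges(data=True)), default=1.0)
    return DistanceNetwork(graph=g, cutoff=cutoff, metric_mode="closest_atom")


def _triangle(w1, w2, w3) -> DistanceNetwork:
    g = nx.Graph()
    g.add_edge(0, 1, weight=w1)
    g.add_edge(1, 2, weight=w2)
    g.add_edge(0, 2, weight=w3)
    return _network_from(g)


class TestDistanceNetwork:
    def test_collinear_chain_counts(self, collinear5):
        assert distance_network(collinear5, 7.0).n_edges == 4
        assert distance_network(collinear5, 8.0).n_edges == 7

    def test_tiny_cutoff_keeps_isolated_nodes(self, collinear5):
        net = distance_network(collinear5, 0.5)
        assert net.n_edges == 0
        assert net.n_nodes == 5

    def test_weights_positive_and_at_most_cutoff(self, collinear5):
        net = distance_network(collinear5, 8.0)
        for _, _, w in net.edges():
            assert 0 < w <= 8.0

    def test_modes_agree_on_ca_only_structures(self, collinear5):
        a = distance_network(collinear5, 8.0, "closest_atom")
        b = distance_network(collinear5, 8.0, "c_alpha")
        assert set(a.graph.edges) == set(b.graph.edges)

    def test_closest_atom_uses_minimum_atom_pair(self):
        s = fixtures.make_cys_pair(2.05)
        net = distance_network(s, 30.0)
        (u, v, w), = net.edges()
        assert w == pytest.approx(2.05, abs=1e-6)  # SG-SG is the closest pair

    def test_hetero_residues_excluded(self):
        from prokit.structure import parse_pdb, write_pdb

        s = fixtures.make_collinear_chain(3)
        text = write_pdb(s).replace(
            "END",
            "HETATM   99  O   HOH A  50       3.800   1.000   0.000"
            "  1.00  0.00           O\nEND",
        )
        net = distance_network(parse_pdb(text), 8.0)
        assert net.n_nodes == 3

    def test_min_separation_excludes_neighbors(self, collinear5):
        net = distance_network(collinear5, 8.0, min_separation=1)
        assert net.n_edges == 3  # only the i,i+2 pairs at 7.6 A

    def test_invalid_cutoff_rejected(self, collinear5):
        with pytest.raises(ValueError):
            distance_network(collinear5, 0.0)

    def test_contact_map_is_alias(self, collinear5):
        a = contact_map(collinear5, 7.0)
        b = distance_network(collinear5, 7.0)
        assert set(a.graph.edges) == set(b.graph.edges)
        # out-of-range cutoff is advisory only
        assert contact_map(collinear5, 4.0).n_edges == 4


class TestThreshold:
    def test_lowering_cutoff_drops_long_edges(self, collinear5):
        net8 = distance_network(collinear5, 8.0)
        net7 = threshold_sparsify(net8, 7.0)
        assert net7.n_edges == 4
        assert net7.n_nodes == 5

    def test_identity_at_original_cutoff(self, collinear5):
        net = distance_network(collinear5, 8.0)
        same = threshold_sparsify(net, 8.0)
        assert set(same.graph.edges) == set(net.graph.edges)

    def test_threshold_zero_empties_edges(self, collinear5):
        net = distance_network(collinear5, 8.0)
        assert threshold_sparsify(net, 0.0).n_edges == 0

    def test_raising_cutoff_rejected(self, collinear5):
        net = distance_network(collinear5, 7.0)
        with pytest.raises(ValueError, match="cannot add"):
            threshold_sparsify(net, 9.0)

    def test_composition_equals_min_cutoff(self, collinear5):
        net = distance_network(collinear5, 8.0)
        a = threshold_sparsify(threshold_sparsify(net, 7.6), 4.0)
        b = threshold_sparsify(net, 4.0)
        assert set(a.graph.edges) == set(b.graph.edges)


class TestBackbone:
    def test_pythagorean_triangle_tie_kept(self):
        result = generalized_backbone(_triangle(3, 4, 5), p=2)
        assert result.removed_edges == set()

    def test_triangle_semi_metric_edge_removed_only_for_p2(self):
        net = _triangle(3, 4, 6)
        assert generalized_backbone(net, 2).removed_edges == {(0, 2)}
        assert generalized_backbone(net, 1).removed_edges == set()

    def test_trees_fully_kept_for_all_p(self):
        g = nx.random_labeled_tree(12, seed=5)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0 + (u + v) % 5
        net = _network_from(g)
        for p in (1, 2, 7.5, math.inf):
            assert generalized_backbone(net, p).removed_edges == set()

    def test_empty_network(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        result = euclidean_backbone(DistanceNetwork(g, 5.0))
        assert result.kept_edges == set() and result.removed_edges == set()

    def test_p_below_one_rejected(self):
        with pytest.raises(ValueError):
            generalized_backbone(_triangle(3, 4, 5), 0.5)

    def test_euclidean_is_p2_alias(self):
        net = _triangle(3, 4, 6)
        assert euclidean_backbone(net).kept_edges == \
            generalized_backbone(net, 2.0).kept_edges

    def test_matches_exhaustive_path_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            g = random_connected_graph(rng)
            net = _network_from(g)
            for p in (1.0, 2.0, math.inf):
                kept, removed = brute_force_backbone(g, p)
                result = generalized_backbone(net, p)
                assert result.kept_edges == kept
                assert result.removed_edges == removed

    def test_structural_guarantees_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            g = random_connected_graph(rng)
            net = _network_from(g)
            results = {p: generalized_backbone(net, p)
                       for p in (1.0, 2.0, math.inf)}
            for result in results.values():
                # partition
                all_edges = {tuple(sorted(e)) for e in g.edges}
                assert result.kept_edges | result.removed_edges == all_edges
                assert not result.kept_edges & result.removed_edges
                # connectivity preserved
                kept = result.kept_network()
                assert (sorted(map(sorted, nx.connected_components(kept.graph)))
                        == sorted(map(sorted, nx.connected_components(g))))
                # idempotence
                again = generalized_backbone(kept, result.p)
                assert again.removed_edges == set()
            # nesting: removals grow with p
            assert results[math.inf].kept_edges <= results[2.0].kept_edges
            assert results[2.0].kept_edges <= results[1.0].kept_edges


class TestRegionGraph:
    def _table(self, annotations, length=20):
        return project_to_residues(annotations, length)

    def test_overlapping_regions_weight_zero(self, collinear5):
        table = self._table([SiteAnnotation("region", 1, 3),
                             SiteAnnotation("region", 3, 5)], 5)
        rg = region_distance_graph(collinear5, table)
        (u, v, d), = ((u, v, d["weight"]) for u, v, d in rg.graph.edges(data=True))
        assert d == 0.0

    def test_single_residue_nodes_reduce_to_distance(self, collinear5):
        table = self._table([SiteAnnotation("binding", 1, 1),
                             SiteAnnotation("binding", 5, 5)], 5)
        rg = region_distance_graph(collinear5, table)
        (_, _, d), = rg.graph.edges(data="weight")
        assert d == pytest.approx(4 * 3.8)

    def test_disjoint_regions_match_brute_force(self):
        chain = fixtures.make_collinear_chain(12)
        anns = [SiteAnnotation("region", 1, 3),
                SiteAnnotation("region", 5, 6),
                SiteAnnotation("region", 9, 12)]
        rg = region_distance_graph(chain, self._table(anns, 12))
        coords = {r.seq_number: r.atoms[0].coords for r in chain.residues}
        for u, v, d in rg.graph.edges(data="weight"):
            lo_u, hi_u = map(int, u.label.split(":")[1].split("-"))
            lo_v, hi_v = map(int, v.label.split(":")[1].split("-"))
            expected = min(
                np.linalg.norm(coords[i] - coords[j])
                for i in range(lo_u, hi_u + 1)
                for j in range(lo_v, hi_v + 1)
            )
            assert d == pytest.approx(expected)

    def test_unresolved_annotation_dropped_with_warning(self, collinear5):
        table = self._table([SiteAnnotation("region", 1, 2),
                             SiteAnnotation("region", 10, 12)], 12)
        with pytest.warns(UserWarning, match="dropped"):
            rg = region_distance_graph(collinear5, table)
        assert rg.graph.number_of_nodes() == 1
        assert rg.dropped == ["region:10-12"]

    def test_max_distance_prunes_edges(self):
        chain = fixtures.make_collinear_chain(12)
        anns = [SiteAnnotation("binding", 1, 1),
                SiteAnnotation("binding", 6, 6),
                SiteAnnotation("binding", 12, 12)]
        rg = region_distance_graph(chain, self._table(anns, 12),
                                   max_distance=20.0)
        assert rg.graph.number_of_edges() == 1  # only the 5-step pair (19 A)


class TestExport:
    def test_edge_count_and_round_trip(self, collinear5):
        net = distance_network(collinear5, 7.0)
        df = export_edgelist(net)
        assert len(df) == 4
        assert list(df.columns) == ["u", "v", "weight"]
        assert read_edgelist(df) == {
            tuple(sorted((u.label, v.label))) for u, v in net.graph.edges
        }

    def test_backbone_export_has_kept_flag(self):
        result = generalized_backbone(_triangle(3, 4, 6), 2)
        df = export_edgelist(result)
        assert list(df.columns) == ["u", "v", "weight", "kept"]
        assert set(df["kept"]) == {0, 1}
        assert df["kept"].sum() == 2

    def test_weights_rounded_to_4_decimals(self, collinear5):
        df = export_edgelist(distance_network(collinear5, 8.0))
        assert (df["weight"] == df["weight"].round(4)).all()

    def test_adjacency_matrix_symmetric(self, collinear5):
        mat = adjacency_matrix(distance_network(collinear5, 8.0))
        assert mat.shape == (5, 5)
        assert (mat.values == mat.values.T).all()
        assert mat.values.diagonal().sum() == 0.0
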