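"""Graph assembly, regulatory profiles, path lengths and topology metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tfnresponse as tfn
from tfnresponse.network import (
    InteractionRecord,
    UnitAnnotation,
    records_from_frame,
    annotations_from_frame,
)

from conftest import random_tfn


def make_records(rows):
    return [InteractionRecord(*r) for r in rows]


def unit(unit_id, members, kind="operon"):
    return UnitAnnotation(unit_id, kind, tuple(members))


# ---------------------------------------------------------------------------
# parsing

class TestParseInteractions:
    def test_token_mapping_and_order(self, tmp_path):
        f = tmp_path / "ints.tsv"
        f.write_text(
            "regulator\ttarget\ttarget_kind\teffect\n"
            "crp\taraB\tgene\t+\n"
            "fis\trrnB-operon\toperon\t+-\n"
            "lacI\tlacZ\tgene\t-\n"
        )
        recs = tfn.parse_interactions(f)
        assert len(recs) == 3
        assert [r.effect for r in recs] == [1, 0, -1]
        assert recs[0].regulator == "crp" and recs[0].target_kind == "gene"

    def test_unknown_effect_token_names_row(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("regulator\ttarget\ttarget_kind\teffect\n"
                     "crp\taraB\tgene\t+\n"
                     "fis\tx\tgene\t++\n")
        with pytest.raises(ValueError, match="row 2"):
            tfn.parse_interactions(f)

    def test_unknown_target_kind_is_hard_error(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("regulator\ttarget\ttarget_kind\teffect\n"
                     "crp\tx\tpromoter\t+\n")
        with pytest.raises(ValueError, match="target_kind"):
            tfn.parse_interactions(f)

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            InteractionRecord("", "x", "gene", 1)
        with pytest.raises(ValueError):
            InteractionRecord("a", "x", "gene", 2)


# ---------------------------------------------------------------------------
# operon/TU expansion

class TestExpandToGeneGraph:
    def test_unit_record_fans_out_to_all_members(self):
        recs = make_records([("A", "op1", "operon", 1)])
        units = {"op1": unit("op1", ["x1", "x2"])}
        g = tfn.expand_to_gene_graph(recs, units)
        assert set(g.edges()) == {("a", "x1", 1), ("a", "x2", 1)}

    def test_conflicting_signs_merge_to_zero(self):
        recs = make_records([("A", "g", "gene", 1), ("A", "tu1", "tu", -1)])
        units = {"tu1": unit("tu1", ["g"], kind="tu")}
        g = tfn.expand_to_gene_graph(recs, units)
        assert g.edges() == [("a", "g", 0)]

    def test_signed_record_wins_over_unknown(self):
        recs = make_records([("A", "g", "gene", 0), ("A", "g", "gene", -1)])
        g = tfn.expand_to_gene_graph(recs, {})
        assert g.edges() == [("a", "g", -1)]

    def test_fanout_count_brute_force(self):
        # 2 TFs x one 3-gene operon each, no overlaps -> 6 edges
        recs = make_records([("A", "op1", "operon", 1), ("B", "op2", "operon", -1)])
        units = {"op1": unit("op1", ["x1", "x2", "x3"]),
                 "op2": unit("op2", ["y1", "y2", "y3"])}
        g = tfn.expand_to_gene_graph(recs, units)
        assert g.n_edges() == 6

    def test_idempotent_on_gene_level_records(self):
        recs = make_records([("A", "b", "gene", 1), ("B", "c", "gene", -1)])
        g1 = tfn.expand_to_gene_graph(recs, {})
        again = [InteractionRecord(u, v, "gene", r) for u, v, r in g1.edges()]
        g2 = tfn.expand_to_gene_graph(again, {})
        assert g1 == g2

    def test_missing_annotation_is_hard_error(self):
        recs = make_records([("A", "op9", "operon", 1)])
        with pytest.raises(KeyError, match="op9"):
            tfn.expand_to_gene_graph(recs, {})

    def test_unresolvable_regulator_skipped_with_warning(self, caplog):
        recs = make_records([("Ghost", "b", "gene", 1), ("A", "b", "gene", 1)])
        with caplog.at_level("WARNING"):
            g = tfn.expand_to_gene_graph(recs, {}, known_genes=["a", "b"])
        assert g.edges() == [("a", "b", 1)]
        assert "skipped" in caplog.text

    def test_synonym_resolution_and_normalization(self):
        recs = make_records([("CRP", "AraB", "gene", 1)])
        g = tfn.expand_to_gene_graph(recs, {}, synonyms={"CRP": "crp"})
        assert g.edges() == [("crp", "arab", 1)]


# ---------------------------------------------------------------------------
# regulatory profiles

class TestRegulatoryProfile:
    def test_bias_arithmetic(self):
        g = tfn.TFNGraph.from_edges([
            ("t1", "x", 1), ("t2", "x", 1), ("t3", "x", -1),
            ("t1", "y", 1), ("t3", "y", -1),
        ])
        prof = tfn.regulatory_profile(g, ["x", "y", "z"])
        assert prof.loc["x", "k_tf"] == 3 and prof.loc["x", "b"] == 1
        assert prof.loc["y", "k_tf"] == 2 and prof.loc["y", "b"] == 0
        assert (prof.loc["z"] == 0).all()

    def test_empty_universe_errors(self, toy_graph):
        with pytest.raises(ValueError):
            tfn.regulatory_profile(toy_graph, [])

    def test_matches_edge_list_scan_on_random_graphs(self, rng):
        for _ in range(30):
            g = random_tfn(rng, int(rng.integers(5, 50)))
            prof = tfn.regulatory_profile(g, g.nodes)
            # independent oracle: plain scan of the edge list
            ksum = {v: 0 for v in g.nodes}
            rsum = {v: 0 for v in g.nodes}
            for u, v, r in g.edges():
                ksum[v] += 1
                rsum[v] += r
            for v in g.nodes:
                assert prof.loc[v, "k_tf"] == ksum[v]
                assert prof.loc[v, "sum_r"] == rsum[v]
                assert prof.loc[v, "b"] == abs(rsum[v])

    def test_ktf_conservation_and_bias_bound(self, rng):
        g = random_tfn(rng, 40)
        prof = tfn.regulatory_profile(g, g.nodes)
        assert prof["k_tf"].sum() == g.n_edges()
        assert (prof["b"] <= prof["k_tf"]).all()

    def test_removing_one_activator_decrements_sum(self):
        g = tfn.TFNGraph.from_edges([("t1", "x", 1), ("t2", "x", 1)])
        before = tfn.regulatory_profile(g, ["x"]).loc["x", "sum_r"]
        g.g.remove_edge("t1", "x")
        after = tfn.regulatory_profile(g, ["x"]).loc["x", "sum_r"]
        assert before - after == 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5),
                              st.sampled_from([-1, 0, 1])), max_size=20))
    def test_parity_property_without_unknowns(self, raw_edges):
        """With all r != 0, K_TF - b equals twice the cancelled
        activator/repressor pairs, hence is always even."""
        edges = {}
        for u, v, r in raw_edges:
            if r != 0:
                edges[(f"t{u}", f"g{v}")] = r
        if not edges:
            return
        g = tfn.TFNGraph.from_edges([(u, v, r) for (u, v), r in edges.items()])
        prof = tfn.regulatory_profile(g, g.nodes)
        for gene in prof.index:
            inputs = [r for _, r in g.in_inputs(gene)]
            n_act = sum(1 for r in inputs if r == 1)
            n_rep = sum(1 for r in inputs if r == -1)
            k, b = prof.loc[gene, "k_tf"], prof.loc[gene, "b"]
            assert k - b == 2 * min(n_act, n_rep)
            assert (k - b) % 2 == 0


# ---------------------------------------------------------------------------
# path lengths

class TestMinPathLengths:
    def test_chain(self):
        g = tfn.TFNGraph.from_edges([("a", "b", 1), ("b", "c", 1)])
        pairs = tfn.min_path_lengths(g)
        got = set(map(tuple, pairs.to_numpy()))
        assert got == {("a", "b", 1), ("b", "c", 1), ("a", "c", 2)}

    def test_minimum_wins(self):
        g = tfn.TFNGraph.from_edges([("a", "b", 1), ("a", "c", 1), ("b", "c", 1)])
        pairs = tfn.min_path_lengths(g).set_index(["input_gene", "output_gene"])
        assert pairs.loc[("a", "c"), "L"] == 1

    def test_self_pairs_excluded(self):
        g = tfn.TFNGraph.from_edges([("a", "b", 1), ("b", "a", 1), ("a", "a", 1)])
        pairs = tfn.min_path_lengths(g)
        assert not (pairs["input_gene"] == pairs["output_gene"]).any()

    def test_matches_floyd_warshall_on_random_graphs(self, rng):
        from scipy.sparse.csgraph import shortest_path

        for _ in range(20):
            g = random_tfn(rng, 30)
            nodes = sorted(g.nodes)
            idx = {v: i for i, v in enumerate(nodes)}
            adj = np.zeros((len(nodes), len(nodes)))
            for u, v, _ in g.edges():
                adj[idx[u], idx[v]] = 1
            dist = shortest_path(adj, method="FW", unweighted=True)
            expected = {
                (u, v, int(dist[idx[u], idx[v]]))
                for u in nodes for v in nodes
                if u != v and np.isfinite(dist[idx[u], idx[v]])
                and 1 <= dist[idx[u], idx[v]] <= 4
            }
            got = set(map(tuple, tfn.min_path_lengths(g, max_L=4).to_numpy()))
            assert got == expected


# ---------------------------------------------------------------------------
# topology metrics

class TestTopologyMetrics:
    def test_star(self):
        g = tfn.TFNGraph.from_edges([("tf", f"g{i}", 1) for i in range(5)])
        table, summary = tfn.topology_metrics(g)
        assert table.loc["tf", "out_degree"] == 5
        assert (table.loc[[f"g{i}" for i in range(5)], "in_degree"] == 1).all()
        assert summary["n_self_loops"] == 0
        assert summary["n_edges"] == 5 and summary["n_connected_components"] == 1

    def test_triangle_cycle_symmetry(self):
        g = tfn.TFNGraph.from_edges([("a", "b", 1), ("b", "c", 1), ("c", "a", 1)])
        table, _ = tfn.topology_metrics(g)
        assert table["betweenness"].nunique() == 1
        assert table["stress_centrality"].nunique() == 1
        assert (table["eccentricity"] == 2).all()

    def test_self_loops_counted(self):
        g = tfn.TFNGraph.from_edges([("a", "a", 1), ("a", "b", 1)])
        _, summary = tfn.topology_metrics(g)
        assert summary["n_self_loops"] == 1

    def test_stress_matches_path_enumeration(self, rng):
        import networkx as nx

        for _ in range(10):
            g = random_tfn(rng, 9, p_edge=0.25)
            table, _ = tfn.topology_metrics(g)
            # oracle: enumerate every shortest path and count pass-throughs
            counts = {v: 0 for v in g.nodes}
            for s in g.nodes:
                for t in g.nodes:
                    if s == t or not nx.has_path(g.g, s, t):
                        continue
                    for path in nx.all_shortest_paths(g.g, s, t):
                        for v in path[1:-1]:
                            counts[v] += 1
            for v in g.nodes:
                assert table.loc[v, "stress_centrality"] == counts[v]

    def test_in_degree_equals_ktf(self, rng):
        g = random_tfn(rng, 25)
        table, _ = tfn.topology_metrics(g, include_stress=False)
        prof = tfn.regulatory_profile(g, g.nodes)
        assert (table["in_degree"] == prof.loc[table.index, "k_tf"]).all()


# ---------------------------------------------------------------------------
# export / import

class TestGraphRoundTrip:
    @pytest.mark.parametrize("fmt", ["tsv", "graphml"])
    def test_round_trip_preserves_signed_edges(self, toy_graph, tmp_path, fmt):
        path = tmp_path / f"g.{fmt}"
        tfn.export_graph(toy_graph, path, format=fmt)
        back = tfn.import_graph(path, format=fmt)
        assert back == toy_graph

    def test_empty_graph_exports(self, tmp_path):
        g = tfn.TFNGraph()
        path = tmp_path / "empty.tsv"
        tfn.export_graph(g, path)
        assert tfn.import_graph(path).n_edges() == 0

    def test_unknown_format_errors(self, toy_graph, tmp_path):
        with pytest.raises(ValueError):
            tfn.export_graph(toy_graph, tmp_path / "g.bin", format="pickle")
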