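import networkx as nx
import numpy as np
import pandas as pd
import pytest

from malani.data import MutationTable, PPINetwork
from malani.piemin import build_pie_min, mutation_landscape, shortest_path


def ppi_from_edges(edges):
    return PPINetwork(graph=nx.Graph(edges))


PATH_GRAPH = ppi_from_edges([("a", "b"), ("b", "c"), ("c", "d")])


class TestShortestPath:
    def test_path_graph(self):
        rec = shortest_path(PATH_GRAPH, "a", "d")
        assert rec.status == "found"
        assert rec.path == ["a", "b", "c", "d"]
        assert rec.length == 2  # interior nodes only

    def test_adjacent_pair_zero_interior(self):
        rec = shortest_path(PATH_GRAPH, "a", "b")
        assert rec.path == ["a", "b"] and rec.length == 0

    def test_disconnected(self):
        net = ppi_from_edges([("a", "b"), ("c", "d")])
        assert shortest_path(net, "a", "d").status == "disconnected"

    def test_missing_endpoint(self):
        assert shortest_path(PATH_GRAPH, "a", "zz").status == "endpoint_missing"

    def test_lexicographic_tie_break(self):
        # two length-2 routes a-b-d and a-c-d: the smaller interior node wins
        net = ppi_from_edges([("a", "c"), ("c", "d"), ("a", "b"), ("b", "d")])
        assert shortest_path(net, "a", "d").path == ["a", "b", "d"]

    def test_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(30):
            g = nx.gnp_random_graph(25, 0.12, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, lambda i: f"n{i:02d}")
            net = PPINetwork(graph=g)
            nodes = sorted(g.nodes)
            for _ in range(5):
                a, b = rng.choice(nodes, 2, replace=False)
                rec = shortest_path(net, a, b)
                if nx.has_path(g, a, b):
                    assert rec.status == "found"
                    assert len(rec.path) - 1 == nx.shortest_path_length(g, a, b)
                else:
                    assert rec.status == "disconnected"


class TestBuildPieMin:
    def test_single_edge_expansion(self):
        min_net = nx.Graph([("a", "d")])
        pm, records = build_pie_min(min_net, PATH_GRAPH)
        assert pm.genes == {"a", "b", "c", "d"}
        assert pm.node_frequency["b"] == 1 and pm.node_frequency["c"] == 1
        assert pm.node_frequency["a"] == 0  # endpoints not counted by default

    def test_shared_interior_node_counts_twice(self):
        ppi = ppi_from_edges(
            [("a", "m"), ("m", "b"), ("c", "m"), ("m", "d")]
        )
        min_net = nx.Graph([("a", "b"), ("c", "d")])
        pm, _ = build_pie_min(min_net, ppi)
        assert pm.node_frequency["m"] == 2

    def test_adjacent_pair_adds_only_edge(self):
        min_net = nx.Graph([("a", "b")])
        pm, records = build_pie_min(min_net, PATH_GRAPH)
        assert pm.genes == {"a", "b"}
        assert records[0].length == 0

    def test_endpoint_counting_flag(self):
        min_net = nx.Graph([("a", "d")])
        pm, _ = build_pie_min(min_net, PATH_GRAPH, count_endpoints=True)
        assert pm.node_frequency["a"] == 1 and pm.node_frequency["b"] == 1

    def test_unmappable_pairs_skipped(self):
        min_net = nx.Graph([("a", "d"), ("a", "zz")])
        pm, records = build_pie_min(min_net, PATH_GRAPH)
        status = {r.pair: r.status for r in records}
        assert status[("a", "zz")] == "endpoint_missing"
        assert "zz" not in pm.genes

    def test_node_set_is_exactly_endpoints_plus_interiors(self):
        rng = np.random.default_rng(1)
        g = nx.relabel_nodes(
            nx.barabasi_albert_graph(40, 2, seed=3), lambda i: f"n{i:02d}"
        )
        ppi = PPINetwork(graph=g)
        nodes = sorted(g.nodes)
        pairs = [tuple(rng.choice(nodes, 2, replace=False)) for _ in range(6)]
        min_net = nx.Graph(pairs)
        pm, records = build_pie_min(min_net, ppi)
        expected = set()
        for r in records:
            if r.status == "found":
                expected |= set(r.path)
        assert pm.genes == expected


class TestLandscape:
    def make_muts(self, mapping):
        rows = [(g, t) for g, types in mapping.items() for t in types]
        return MutationTable(
            records=pd.DataFrame(rows, columns=["gene", "mutation_type"])
        )

    def test_type_counts_and_multi_type(self):
        ppi = PATH_GRAPH
        min_net = nx.Graph([("a", "d")])
        pm, _ = build_pie_min(min_net, ppi)
        muts = self.make_muts(
            {
                "a": {"missense"},
                "b": {"missense", "silent"},
                "c": {"missense", "nonsense", "splicing"},
                "zz": {"missense"},  # outside the PIE-MIN: ignored
            }
        )
        summary = mutation_landscape(pm, muts, ppi)
        assert summary.type_gene_counts["missense"] == 3
        assert summary.multi_type_genes == ["c"]

    def test_cumulative_neighbors(self):
        ppi = ppi_from_edges(
            [("a", x) for x in "bcde"] + [("f", x) for x in "aghijklm"]
        )
        pm, _ = build_pie_min(nx.Graph([("a", "f")]), ppi)
        muts = self.make_muts({"a": {"missense"}, "f": {"missense"}})
        summary = mutation_landscape(pm, muts, ppi)
        # degree(a)=5, degree(f)=8
        assert summary.cumulative_neighbors["missense"] == 13

    def test_twelve_node_fixture_matches_enumeration(self):
        """Hand-built fixture: counts verified by exhaustive enumeration."""
        edges = [
            ("g01", "g02"), ("g02", "g03"), ("g03", "g04"), ("g04", "g05"),
            ("g05", "g06"), ("g02", "g07"), ("g07", "g08"), ("g08", "g09"),
            ("g09", "g10"), ("g03", "g11"), ("g11", "g12"), ("g12", "g06"),
        ]
        ppi = ppi_from_edges(edges)
        min_net = nx.Graph([("g01", "g06"), ("g01", "g10")])
        pm, records = build_pie_min(min_net, ppi)
        mapping = {
            "g01": {"missense", "silent", "nonsense"},
            "g02": {"missense"},
            "g03": {"silent"},
            "g09": {"missense", "amplified"},
            "g12": {"intronic"},
        }
        muts = self.make_muts(mapping)
        summary = mutation_landscape(pm, muts, ppi)
        # enumeration oracle: recompute from scratch with plain loops
        pie_genes = set()
        for r in records:
            pie_genes |= set(r.path)
        counts = {}
        cum = {}
        for t in {"missense", "silent", "nonsense", "amplified", "intronic"}:
            carriers = [g for g in sorted(pie_genes) if t in mapping.get(g, set())]
            if carriers:
                counts[t] = len(carriers)
                cum[t] = sum(dict(ppi.graph.degree)[g] for g in carriers)
        multi = sorted(
            g for g in pie_genes if len(mapping.get(g, set())) >= 3
        )
        assert summary.type_gene_counts == counts
        assert summary.cumulative_neighbors == cum
        assert summary.multi_type_genes == multi

    def test_q3_subnetwork_filter(self):
        ppi = PATH_GRAPH
        pm, _ = build_pie_min(nx.Graph([("a", "d")]), ppi)
        muts = self.make_muts({"a": {"missense"}})
        from malani.annotate import classify_genes, fold_change_status
        from malani.data import ExpressionDataset

        ds = ExpressionDataset(
            ["a", "b", "c", "d"],
            ["c1", "c2", "n1", "n2"],
            np.array([[9.0, 9.0, 1.0, 1.0]] + [[1.0, 1.0, 1.0, 1.0]] * 3),
            np.array(["cancer", "cancer", "normal", "normal"], dtype=object),
        )
        de = fold_change_status(ds)
        labels = classify_genes(pm.graph, de, None)
        pvalues = {"a": 0.01, "b": 0.9, "c": 0.5, "d": 0.2}
        summary = mutation_landscape(
            pm, muts, ppi, labels=labels, de=de, pvalues=pvalues
        )
        # candidates: a (DE) and b,c,d (class II) -> q3 of (.01,.9,.5,.2)
        assert summary.pvalue_q3 == pytest.approx(0.6, abs=1e-9)
        assert set(summary.subnetwork.nodes) == {"b"}
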