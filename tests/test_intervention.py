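"""Multi-pathway deletion metrics and the hub-expectation diagnostic."""

import networkx as nx
import numpy as np
import pytest

from pcnet.containers import PathwayAnnotation
from pcnet.intervention import (
    compare_target_sets,
    hub_expectation,
    remove_pathways,
    select_category_set,
)
from pcnet.netstats import enumerate_circles
from conftest import gene_network, pathway_network, random_graph


def net_from_graph(g):
    return pathway_network([(u, v, 0.5) for u, v in g.edges()], extra_nodes=g.nodes())


class TestRemovePathways:
    def test_deleting_everything(self):
        pn = net_from_graph(nx.complete_graph(["A", "B", "C"]))
        rep = remove_pathways(pn, {"A", "B", "C"})
        assert rep.nodes_after_deletion == 0
        assert rep.incident_edge_fraction == pytest.approx(1.0)
        assert rep.first_neighbors == set()

    def test_star_center(self):
        pn = net_from_graph(nx.star_graph(["hub", "a", "b", "c", "d"]))
        rep = remove_pathways(pn, {"hub"})
        assert rep.first_neighbor_fraction == pytest.approx(4 / 5)
        assert rep.isolated_after_deletion == {"a", "b", "c", "d"}

    def test_hand_computed_toy(self):
        # 6 nodes: triangle A-B-C, path C-D-E, isolated F
        pn = net_from_graph(
            nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"), ("D", "E")])
        )
        pn.graph.add_node("F")
        rep = remove_pathways(pn, {"A", "D"}, hub_k=2)
        assert rep.first_neighbors == {"B", "C", "E"}
        assert rep.first_neighbor_fraction == pytest.approx(3 / 6)
        assert rep.incident_edge_fraction == pytest.approx(4 / 5)
        assert rep.nodes_after_deletion == 4
        assert rep.isolated_after_deletion == {"E", "F"}
        assert rep.new_hubs == ["B", "C"]
        assert rep.circle_fraction == pytest.approx(1.0)  # the only triangle has A

    def test_unknown_targets_ignored_but_all_unknown_fatal(self, caplog):
        pn = net_from_graph(nx.path_graph(["A", "B", "C"]))
        rep = remove_pathways(pn, {"A", "ghost"})
        assert rep.target_set == {"A"}
        with pytest.raises(ValueError):
            remove_pathways(pn, {"ghost"})

    def test_order_invariance(self, rng):
        pn = net_from_graph(random_graph(rng, p_range=(0.3, 0.5)))
        nodes = sorted(pn.graph.nodes)[:3]
        a = remove_pathways(pn, nodes)
        b = remove_pathways(pn, list(reversed(nodes)))
        assert a == b

    def test_circle_fraction_equals_count_ratio_complement(self, rng):
        for _ in range(30):
            g = random_graph(rng, p_range=(0.3, 0.6))
            pn = net_from_graph(g)
            total = len(enumerate_circles(g, 3))
            if total == 0:
                continue
            targets = set(
                rng.choice(sorted(g.nodes), size=min(3, g.number_of_nodes()), replace=False)
            )
            if not targets & set(g.nodes):
                continue
            rep = remove_pathways(pn, targets)
            deleted = g.copy()
            deleted.remove_nodes_from(targets)
            remaining = len(enumerate_circles(deleted, 3))
            assert rep.circle_fraction == pytest.approx(1 - remaining / total)


class TestCompareTargetSets:
    def test_identical_sets_identical_rows(self):
        pn = net_from_graph(nx.complete_graph(["A", "B", "C", "D"]))
        table = compare_target_sets(pn, {"x": {"A"}, "y": {"A"}})
        cols = [c for c in table.columns if c != "new_hubs"]
        assert table.loc["x", cols].equals(table.loc["y", cols])

    def test_nested_sets_monotone_incident_fraction(self, rng):
        for _ in range(20):
            g = random_graph(rng, p_range=(0.3, 0.5))
            pn = net_from_graph(g)
            nodes = sorted(g.nodes)
            a = set(nodes[:2])
            b = set(nodes[:4])
            table = compare_target_sets(pn, {"A": a, "B": b})
            assert (
                table.loc["A", "incident_edge_fraction"]
                <= table.loc["B", "incident_edge_fraction"]
            )

    def test_ranking_matches_hand_computation(self):
        # star: center is in no triangle network; add triangle X-Y-Z off to the side
        g = nx.Graph([("X", "Y"), ("Y", "Z"), ("X", "Z"), ("hub", "X"), ("hub", "W")])
        pn = net_from_graph(g)
        table = compare_target_sets(pn, {"tri": {"Y"}, "leaf": {"W"}, "two": {"Y", "Z"}})
        assert list(table.index[:2]) == ["tri", "two"] or list(table.index[:2]) == ["two", "tri"]
        assert table.loc["leaf", "circle_fraction"] == 0.0


class TestSelectCategorySet:
    def ann(self):
        return PathwayAnnotation(
            {p: {f"g{p}"} for p in ("I1", "I2", "I3", "M1")},
            {"I1": "Immune System", "I2": "Immune System", "I3": "Immune System",
             "M1": "Metabolism"},
        )

    def network(self):
        # degrees: I2=4, I1=2, I3=2, M1=...
        g = nx.Graph(
            [("I2", x) for x in ("I1", "I3", "M1", "E1")]
            + [("I1", "M1"), ("I3", "E1")]
        )
        return net_from_graph(g)

    def test_highest_degree_of_category(self):
        assert select_category_set(self.network(), self.ann(), "Immune System", 1) == {"I2"}

    def test_tie_rule(self):
        assert select_category_set(self.network(), self.ann(), "Immune System", 2) == {
            "I2",
            "I1",
        }

    def test_k_larger_than_available_warns_and_returns_all(self, caplog):
        with caplog.at_level("WARNING"):
            out = select_category_set(self.network(), self.ann(), "Metabolism", 5)
        assert out == {"M1"}
        assert "Metabolism" in caplog.text

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            select_category_set(self.network(), self.ann(), "Genetic Information", 1)


class TestHubExpectation:
    def test_dominant_pathway_ranks_first(self):
        gcn = gene_network(
            [("g1", "g2", 0.9), ("g1", "g3", 0.9), ("g1", "g4", 0.9), ("g2", "g3", 0.9)]
        )
        ann = PathwayAnnotation(
            {"BIG": {"g1", "g2", "g3"}, "SMALL": {"g4"}}
        )
        pn = pathway_network([("BIG", "SMALL", 0.5)])
        table = hub_expectation(gcn, pn, ann)
        assert table.loc["BIG", "expected_rank"] == 1.0

    def test_symmetric_pathways_have_zero_discrepancy(self):
        gcn = gene_network([("g1", "g2", 0.9), ("g3", "g4", 0.9)])
        ann = PathwayAnnotation({"P1": {"g1", "g2"}, "P2": {"g3", "g4"}})
        pn = pathway_network([("P1", "P2", 0.5)])
        table = hub_expectation(gcn, pn, ann)
        assert (table["discrepancy"] == 0).all()

    def test_constructed_ranking(self):
        # HUBBY has few, low-degree genes but high network degree →
        # more connected than expected (negative discrepancy)
        gcn = gene_network(
            [("a1", "a2", 0.9), ("a1", "a3", 0.9), ("a2", "a3", 0.9), ("b1", "a1", 0.9)],
            extra_nodes=["c1"],
        )
        ann = PathwayAnnotation(
            {"RICH": {"a1", "a2", "a3"}, "HUBBY": {"c1"}, "MID": {"b1"}}
        )
        pn = pathway_network(
            [("HUBBY", "RICH", 0.5), ("HUBBY", "MID", 0.5)]
        )
        table = hub_expectation(gcn, pn, ann)
        assert table.loc["HUBBY", "discrepancy"] < 0
        assert table.loc["RICH", "discrepancy"] > 0
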