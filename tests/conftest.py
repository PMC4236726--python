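"""Shared fixtures and independent brute-force oracles."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from pcnet.containers import GeneNetwork, PathwayAnnotation, PathwayNetwork
from pcnet.netstats import canonical_cycle


def gene_network(edges, extra_nodes=()):
    """Build a GeneNetwork from (g1, g2, r) triples; p/q attrs filled in."""
    g = nx.Graph()
    g.add_nodes_from(extra_nodes)
    for g1, g2, r in edges:
        g.add_edge(g1, g2, r=r, p_raw=0.0, q_fdr=0.0)
    return GeneNetwork(g)


def pathway_network(edges, extra_nodes=()):
    """Build a PathwayNetwork from (a, b, weight) triples."""
    g = nx.Graph()
    g.add_nodes_from(extra_nodes)
    for a, b, w in edges:
        g.add_edge(a, b, weight=w, n_gene_edges=1, p_perm=None)
    return PathwayNetwork(g)


def random_graph(rng, n_max=12, n_min=4, p_range=(0.15, 0.6)):
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(*p_range))
    g = nx.Graph()
    nodes = [f"n{i:02d}" for i in range(n)]
    g.add_nodes_from(nodes)
    for u, v in combinations(nodes, 2):
        if rng.random() < p:
            g.add_edge(u, v)
    return g


def oracle_circles(g, length):
    """Exhaustive subset/ordering enumeration of simple cycles."""
    out = set()
    nodes = sorted(g.nodes)
    if length == 3:
        for trio in combinations(nodes, 3):
            a, b, c = trio
            if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c):
                out.add(trio)
        return out
    for quad in combinations(nodes, 4):
        a, b, c, d = quad
        # the three distinct cyclic orderings of four labelled nodes
        for order in ((a, b, c, d), (a, b, d, c), (a, c, b, d)):
            if all(g.has_edge(order[i], order[(i + 1) % 4]) for i in range(4)):
                out.add(canonical_cycle(order))
    return out


def oracle_aggregate(gcn, annotation):
    """Enumerate every (gene edge × pathway pair) combination directly."""
    pathways = sorted(annotation.pathway_genes)
    weights, counts = {}, {}
    for pa, pb in combinations(pathways, 2):
        genes_a = annotation.pathway_genes[pa]
        genes_b = annotation.pathway_genes[pb]
        rs = []
        for g1, g2, r in gcn.graph.edges.data("r"):
            if (g1 in genes_a and g2 in genes_b) or (g1 in genes_b and g2 in genes_a):
                rs.append(r)
        if rs:
            weights[(pa, pb)] = sum(rs) / len(rs)
            counts[(pa, pb)] = len(rs)
    return weights, counts


def oracle_bh(p):
    """Suffix-minimum BH oracle, deliberately naive."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    ranked = [p[order[i]] * m / (i + 1) for i in range(m)]
    q = [0.0] * m
    for i in range(m):
        q[order[i]] = min(1.0, min(ranked[i:]))
    return np.array(q)


@pytest.fixture
def rng():
    return np.random.default_rng(20240729)


@pytest.fixture
def toy_annotation():
    return PathwayAnnotation(
        pathway_genes={
            "P1": {"g1", "g2"},
            "P2": {"g3", "g4"},
            "P3": {"g2", "g5"},
        },
        pathway_category={"P1": "Immune System", "P2": "Metabolism"},
    )
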