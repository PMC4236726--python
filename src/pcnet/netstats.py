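"""Topological network characteristics.

All metrics are computed on the undirected, unweighted skeleton: node
degree and degree distribution, edge density, local and average clustering,
connected components and the giant component, hub extraction with a
deterministic tie rule, and exhaustive enumeration of 3- and 4-node circles
(simple cycles up to rotation and reflection; chords are permitted in
4-cycles).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import networkx as nx

from .containers import GeneNetwork, PathwayNetwork

__all__ = [
    "FeatureBundle",
    "CircleSet",
    "as_graph",
    "network_features",
    "top_hubs",
    "enumerate_circles",
]

NetworkLike = Union[GeneNetwork, PathwayNetwork, nx.Graph]


def as_graph(network: NetworkLike) -> nx.Graph:
    if isinstance(network, (GeneNetwork, PathwayNetwork)):
        return network.graph
    return network


@dataclass
class FeatureBundle:
    """Scalar and per-node topology metrics of one network."""

    degrees: dict[str, int]
    degree_distribution: dict[int, float]
    edge_density: float
    local_clustering: dict[str, float]
    avg_clustering: float
    components: list[set[str]]
    giant: set[str]

    def scalars(self) -> dict[str, float]:
        """The scalar features compared against permutation nulls."""
        n = len(self.degrees)
        n_edges = sum(self.degrees.values()) // 2
        return {
            "n_nodes": float(n),
            "n_edges": float(n_edges),
            "edge_density": self.edge_density,
            "avg_degree": 2.0 * n_edges / n if n else 0.0,
            "avg_clustering": self.avg_clustering,
            "n_components": float(len(self.components)),
            "giant_size": float(len(self.giant)),
        }

    def write(self, path: Union[str, Path]) -> None:
        with Path(path).open("w") as fh:
            fh.write("feature\tvalue\n")
            for k, v in self.scalars().items():
                fh.write(f"{k}\t{v:.6f}\n")


@dataclass
class CircleSet:
    """Canonical simple cycles of one fixed length.

    Each circle is stored as its canonical node sequence: starting at the
    lexicographically smallest node and proceeding toward its smaller
    cycle-neighbor, so rotations and reflections collapse to one form.
    """

    length: int
    circles: set[tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.circles)

    def containing(self, nodes: set[str]) -> set[tuple[str, ...]]:
        """Circles containing at least one of the given nodes."""
        return {c for c in self.circles if not nodes.isdisjoint(c)}

    def write(self, path: Union[str, Path]) -> None:
        with Path(path).open("w") as fh:
            fh.write("\t".join(f"node_{i+1}" for i in range(self.length)) + "\n")
            for c in sorted(self.circles):
                fh.write("\t".join(c) + "\n")


def canonical_cycle(nodes: tuple[str, ...]) -> tuple[str, ...]:
    """Rotation/reflection-invariant canonical form of a cycle sequence."""
    k = len(nodes)
    start = min(range(k), key=lambda i: nodes[i])
    forward = tuple(nodes[(start + i) % k] for i in range(k))
    backward = tuple(nodes[(start - i) % k] for i in range(k))
    return min(forward, backward)


def network_features(network: NetworkLike) -> FeatureBundle:
    """Compute the full feature bundle on the unweighted skeleton."""
    g = as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute features of an empty network")
    degrees = {n: d for n, d in g.degree()}
    n = len(degrees)
    dist: dict[int, float] = {}
    for d in degrees.values():
        dist[d] = dist.get(d, 0.0) + 1.0 / n
    clustering = {node: float(c) for node, c in nx.clustering(g).items()}
    components = [set(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), min(c)))
    return FeatureBundle(
        degrees=degrees,
        degree_distribution=dist,
        edge_density=float(nx.density(g)),
        local_clustering=clustering,
        avg_clustering=sum(clustering.values()) / n,
        components=components,
        giant=components[0],
    )


def top_hubs(network: NetworkLike, k: int) -> list[str]:
    """The ``k`` highest-degree nodes; ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    g = as_graph(network)
    ranked = sorted(g.degree(), key=lambda nd: (-nd[1], nd[0]))
    return [n for n, _ in ranked[:k]]


def enumerate_circles(network: NetworkLike, length: int) -> CircleSet:
    """All distinct simple cycles of exactly ``length`` ∈ {3, 4}.

    4-cycles may carry chords; counting is inclusive.  Triangles are found
    edge-by-edge via common neighborhoods; 4-cycles via common-neighbor
    pairs across each (ordered-free) node pair, deduplicated through the
    canonical form.
    """
    if length not in (3, 4):
        raise ValueError("circle length must be 3 or 4")
    g = as_graph(network)
    circles: set[tuple[str, ...]] = set()
    if length == 3:
        for u, v in g.edges():
            for w in set(g[u]) & set(g[v]):
                circles.add(tuple(sorted((u, v, w))))
        return CircleSet(3, circles)
    nodes = sorted(g.nodes())
    adj = {n: set(g[n]) for n in nodes}
    for i, u in enumerate(nodes):
        for w in nodes[i + 1 :]:
            common = sorted(adj[u] & adj[w])
            for a in range(len(common)):
                for b in range(a + 1, len(common)):
                    v, x = common[a], common[b]
                    circles.add(canonical_cycle((u, v, w, x)))
    return CircleSet(4, circles)
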