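"""The three redundancy mechanisms.

(1) *Redundant genes*: delete one gene from the gene network, re-aggregate
the pathway network, and contrast a focal pathway's crosstalk before and
after — with p-values recomputed on the identical stored permutations so
the contrast isolates the deletion effect.
(2) *Redundant crosstalk paths*: every common neighbor of a pathway edge's
endpoints closes one 3-node circle through that edge.
(3) *Redundant category circles*: 3-node pathway circles reduced to the
multiset of their members' categories and tallied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .containers import GeneNetwork, PathwayAnnotation, PathwayNetwork, edge_key
from .netstats import CircleSet
from .pcn import (
    NullEnsemble,
    aggregate_pathway_edges,
    edge_significance,
    rerun_null_weights,
)

__all__ = [
    "ChangedEdge",
    "GeneDeletionReport",
    "CategoryCircle",
    "gene_deletion_impact",
    "circles_on_edge",
    "categorize_circles",
]


@dataclass
class ChangedEdge:
    pair: tuple[str, str]
    weight_before: Optional[float]
    weight_after: Optional[float]
    p_before: Optional[float]
    p_after: Optional[float]


@dataclass
class GeneDeletionReport:
    """Effect of deleting one gene on a focal pathway's crosstalk."""

    gene: str
    focal_pathway: str
    degree_before: int
    degree_after: int
    changed_edges: list[ChangedEdge]

    def write(self, path: Union[str, Path]) -> None:
        with Path(path).open("w") as fh:
            fh.write(
                "pathway_a\tpathway_b\tweight_before\tweight_after\tp_before\tp_after\n"
            )
            for e in self.changed_edges:
                cells = [e.pair[0], e.pair[1]] + [
                    "NA" if v is None else "%.6f" % v
                    for v in (e.weight_before, e.weight_after, e.p_before, e.p_after)
                ]
                fh.write("\t".join(cells) + "\n")


def _incident_edges(pn: PathwayNetwork, focal: str) -> dict[tuple[str, str], dict]:
    if focal not in pn.graph:
        return {}
    return {edge_key(focal, nbr): dict(pn.graph.edges[focal, nbr]) for nbr in pn.graph[focal]}


def gene_deletion_impact(
    gcn: GeneNetwork,
    annotation: PathwayAnnotation,
    null: Optional[NullEnsemble],
    gene: str,
    focal_pathway: str,
    recompute_p: bool = True,
) -> GeneDeletionReport:
    """Delete ``gene`` from the gene network and contrast the focal
    pathway's crosstalk before vs after.

    With ``recompute_p`` the stored permutation label assignments are
    re-run on the reduced gene set, so before/after p-values share the same
    Monte-Carlo draw, and degrees are counted on the significant networks;
    without it degrees are counted on the raw aggregated networks and p
    fields are ``None``.
    """
    if gene not in gcn.graph:
        raise KeyError(f"gene {gene!r} not in the gene network")
    if focal_pathway not in annotation.pathway_genes:
        raise KeyError(f"pathway {focal_pathway!r} not in the annotation")
    if recompute_p and null is None:
        raise ValueError("recompute_p requires a null ensemble")
    before_agg = aggregate_pathway_edges(gcn, annotation)
    after_agg = aggregate_pathway_edges(gcn.without_gene(gene), annotation)
    if recompute_p:
        assert null is not None
        before = edge_significance(before_agg, null, null.params.alpha_pcn)
        after_weights = rerun_null_weights(null, drop_genes={gene})
        after = edge_significance(
            after_agg, null, null.params.alpha_pcn, null_weights=after_weights
        )
    else:
        before, after = before_agg, after_agg
    before_inc = _incident_edges(before, focal_pathway)
    after_inc = _incident_edges(after, focal_pathway)
    changed: list[ChangedEdge] = []
    for key in sorted(set(before_inc) | set(after_inc)):
        b = before_inc.get(key)
        a = after_inc.get(key)
        changed.append(
            ChangedEdge(
                pair=key,
                weight_before=None if b is None else b["weight"],
                weight_after=None if a is None else a["weight"],
                p_before=None if b is None else b.get("p_perm"),
                p_after=None if a is None else a.get("p_perm"),
            )
        )
    return GeneDeletionReport(
        gene=gene,
        focal_pathway=focal_pathway,
        degree_before=len(before_inc),
        degree_after=len(after_inc),
        changed_edges=changed,
    )


def circles_on_edge(pcn: PathwayNetwork, pathway_a: str, pathway_b: str) -> list[str]:
    """Third vertices of every 3-node circle through an existing edge.

    Returns the pathways adjacent to both endpoints, sorted; each is one
    redundant path bridging the crosstalk.
    """
    g = pcn.graph
    if not g.has_edge(pathway_a, pathway_b):
        raise KeyError(f"no edge between {pathway_a!r} and {pathway_b!r}")
    return sorted(set(g[pathway_a]) & set(g[pathway_b]))


@dataclass
class CategoryCircle:
    """A 3-node circle type: the sorted multiset of member categories."""

    categories: tuple[str, str, str]
    count: int
    members: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        assert self.count == len(self.members)


def categorize_circles(
    circles: CircleSet, annotation: PathwayAnnotation
) -> list[CategoryCircle]:
    """Group 3-node pathway circles by their category multiset.

    Returns groups sorted by count descending, ties broken
    lexicographically on the category triple.  ``uncategorized`` is a legal
    label, so the counts always sum to the number of input circles.
    """
    if circles.length != 3:
        raise ValueError("category circles are defined for 3-node circles")
    groups: dict[tuple[str, str, str], list[tuple[str, ...]]] = {}
    for circle in circles.circles:
        key = tuple(sorted(annotation.category(p) for p in circle))
        groups.setdefault(key, []).append(circle)
    out = [
        CategoryCircle(categories=k, count=len(v), members=sorted(v))
        for k, v in groups.items()
    ]
    out.sort(key=lambda c: (-c.count, c.categories))
    return out


def write_category_circles(
    category_circles: list[CategoryCircle], path: Union[str, Path]
) -> None:
    with Path(path).open("w") as fh:
        fh.write("category_1\tcategory_2\tcategory_3\tcount\n")
        for c in category_circles:
            fh.write("\t".join(c.categories) + f"\t{c.count}\n")
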