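"""Multi-pathway deletion metrics for comparing candidate target sets.

A drug (or any named pathway set) is modeled as the simultaneous deletion
of its targeted pathways from the pathway network.  Connectivity of the set
is summarized on the *original* network (first-neighbor coverage, incident
edge fraction, 3-node circle participation) and on the deleted network
(remaining nodes, newly isolated nodes, new hubs).  A companion diagnostic
asks whether each pathway hub is explainable from gene-level connectivity
and pathway size alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import GeneNetwork, PathwayAnnotation, PathwayNetwork
from .netstats import enumerate_circles, top_hubs

__all__ = [
    "InterventionReport",
    "remove_pathways",
    "compare_target_sets",
    "select_category_set",
    "hub_expectation",
]

log = logging.getLogger(__name__)


@dataclass
class InterventionReport:
    """Connectivity of a target set and of the network after deleting it.

    All fractions use the original network's node/edge/circle counts as
    denominators; ``first_neighbors`` excludes the targets themselves.
    """

    target_set: set[str]
    first_neighbors: set[str]
    first_neighbor_fraction: float
    incident_edge_fraction: float
    nodes_after_deletion: int
    isolated_after_deletion: set[str]
    new_hubs: list[str]
    circle_fraction: float

    def as_row(self) -> dict:
        return {
            "n_targets": len(self.target_set),
            "first_neighbor_fraction": self.first_neighbor_fraction,
            "incident_edge_fraction": self.incident_edge_fraction,
            "nodes_after_deletion": self.nodes_after_deletion,
            "n_isolated_after_deletion": len(self.isolated_after_deletion),
            "circle_fraction": self.circle_fraction,
            "new_hubs": ";".join(self.new_hubs),
        }


def remove_pathways(
    pcn: PathwayNetwork, targets: Iterable[str], hub_k: int = 10
) -> InterventionReport:
    """Delete a pathway set and measure its network footprint.

    Targets absent from the network are logged and ignored; it is an error
    for every target to be unknown.
    """
    g = pcn.graph
    targets = set(targets)
    if not targets:
        raise ValueError("empty target set")
    present = targets & set(g.nodes)
    missing = targets - present
    if missing:
        log.info("targets absent from the network, ignored: %s", sorted(missing))
    if not present:
        raise ValueError("no target pathway exists in the network")
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    neighbors: set[str] = set()
    for t in present:
        neighbors.update(g[t])
    neighbors -= present
    incident = sum(1 for u, v in g.edges() if u in present or v in present)
    deleted = g.copy()
    deleted.remove_nodes_from(present)
    isolated = {n for n, d in deleted.degree() if d == 0}
    circles = enumerate_circles(g, 3)
    hit = circles.containing(present)
    return InterventionReport(
        target_set=present,
        first_neighbors=neighbors,
        first_neighbor_fraction=len(neighbors) / n_nodes,
        incident_edge_fraction=incident / n_edges if n_edges else 0.0,
        nodes_after_deletion=n_nodes - len(present),
        isolated_after_deletion=isolated,
        new_hubs=top_hubs(deleted, hub_k) if deleted.number_of_nodes() else [],
        circle_fraction=len(hit) / len(circles) if len(circles) else 0.0,
    )


def compare_target_sets(
    pcn: PathwayNetwork, named_sets: Mapping[str, set[str]], hub_k: int = 10
) -> pd.DataFrame:
    """One intervention row per named set, sorted by circle participation.

    All rows share the same denominators (the original network), making the
    metrics directly comparable across drugs, hub sets and category sets.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two named target sets to compare")
    rows = {}
    for name, targets in named_sets.items():
        rows[name] = remove_pathways(pcn, targets, hub_k=hub_k).as_row()
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "target_set"
    return table.sort_values(
        by=["circle_fraction", "first_neighbor_fraction"], ascending=False, kind="stable"
    )


def select_category_set(
    pcn: PathwayNetwork, annotation: PathwayAnnotation, category: str, k: int
) -> set[str]:
    """The ``k`` most connected network pathways of one category.

    Uses the hub tie rule (degree descending, then lexicographic); asking
    for more pathways than the category offers returns them all with a
    warning.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    members = [p for p in pcn.graph.nodes if annotation.category(p) == category]
    if not members:
        raise ValueError(f"no network pathway belongs to category {category!r}")
    if k > len(members):
        log.warning(
            "category %r has only %d network pathways (requested %d)",
            category,
            len(members),
            k,
        )
    ranked = sorted(members, key=lambda p: (-pcn.graph.degree(p), p))
    return set(ranked[:k])


def hub_expectation(
    gcn: GeneNetwork, pcn: PathwayNetwork, annotation: PathwayAnnotation
) -> pd.DataFrame:
    """Is a pathway hub explainable from gene hubs and pathway size?

    For each network pathway with at least one member gene in the gene
    network, two naive predictors are ranked (rank 1 = largest): the summed
    gene-network degree of its member genes, and its member-gene count.
    The expected rank is the rank of the average of those two ranks;
    ``discrepancy = observed_degree_rank − expected_rank``, so positive
    values flag pathways less connected than the naive prediction and
    negative values pathways more connected than predicted.
    """
    gene_degree = dict(gcn.graph.degree())
    records = []
    for p in sorted(pcn.graph.nodes):
        members = annotation.pathway_genes.get(p, set()) & set(gene_degree)
        if not members:
            log.warning("pathway %r has no member gene in the gene network", p)
            continue
        records.append(
            {
                "pathway": p,
                "observed_degree": pcn.graph.degree(p),
                "member_gene_degree_sum": sum(gene_degree[g] for g in members),
                "member_gene_count": len(members),
            }
        )
    if not records:
        raise ValueError("no pathway has member genes in the gene network")
    table = pd.DataFrame.from_records(records).set_index("pathway")
    # rank 1 = largest; ties get average ranks
    rank_deg = rankdata(-table["member_gene_degree_sum"], method="average")
    rank_size = rankdata(-table["member_gene_count"], method="average")
    expected_score = (rank_deg + rank_size) / 2.0
    table["expected_rank"] = rankdata(expected_score, method="average")
    table["observed_degree_rank"] = rankdata(-table["observed_degree"], method="average")
    table["discrepancy"] = table["observed_degree_rank"] - table["expected_rank"]
    return table
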