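"""Core in-memory containers shared by every pipeline stage.

The pipeline moves data through four representations: a genes × samples
expression matrix, a grouping of samples into phenotype groups (e.g. tumor
subtype vs matched non-tumor), a gene co-expression network (genes as nodes,
significant Pearson correlations as edges) and a pathway co-expression
network (pathways as nodes, mean cross-pathway gene correlation as edge
weight).  All identifiers are case-sensitive exact strings; no symbol
aliasing is performed, so the containers stay agnostic of the annotation
source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleGrouping",
    "PathwayAnnotation",
    "DrugTargetMap",
    "GeneNetwork",
    "PathwayNetwork",
    "UNCATEGORIZED",
]

UNCATEGORIZED = "uncategorized"


def _check_unique(ids: Iterable[str], kind: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log-scale expression intensities.

    Parameters
    ----------
    values
        Real matrix, shape ``(n_genes, n_samples)``; all entries finite.
    gene_ids, sample_ids
        Ordered unique identifiers for rows and columns.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids) or n_samples != len(self.sample_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if n_genes < 2:
            raise ValueError("need at least 2 genes")
        if n_samples < 2:
            # correlation stages enforce their own ≥3-sample floor
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message detail
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        idx = self.sample_index(sample_ids)
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), [self.sample_ids[i] for i in idx]
        )

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[idx, :], [self.gene_ids[i] for i in idx], list(self.sample_ids)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))


@dataclass
class SampleGrouping:
    """Assignment of each sample to exactly one phenotype group."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("empty sample grouping")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignment.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples(self, group: str) -> list[str]:
        out = [s for s, g in self.assignment.items() if g == group]
        if not out:
            raise ValueError(f"group {group!r} has no samples")
        return out

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.assignment]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")


@dataclass
class PathwayAnnotation:
    """Gene membership and category label for each pathway.

    A gene may belong to any number of pathways (multi-membership drives the
    pathway-pair aggregation rule).  Pathways missing from the category map
    carry the designated label ``"uncategorized"``.
    """

    pathway_genes: dict[str, set[str]]
    pathway_category: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p, genes in self.pathway_genes.items():
            if not genes:
                raise ValueError(f"pathway {p!r} has an empty gene set")
        for p in self.pathway_genes:
            self.pathway_category.setdefault(p, UNCATEGORIZED)

    @property
    def pathways(self) -> list[str]:
        return list(self.pathway_genes)

    def category(self, pathway: str) -> str:
        return self.pathway_category.get(pathway, UNCATEGORIZED)

    @cached_property
    def gene_pathways(self) -> dict[str, tuple[str, ...]]:
        """Inverse map: gene → sorted tuple of pathways it belongs to."""
        inv: dict[str, list[str]] = {}
        for p, genes in self.pathway_genes.items():
            for g in genes:
                inv.setdefault(g, []).append(p)
        return {g: tuple(sorted(ps)) for g, ps in inv.items()}


@dataclass
class DrugTargetMap:
    """Drug name → set of pathway ids the drug is assumed to knock out."""

    targets: dict[str, set[str]]

    def __post_init__(self) -> None:
        for drug, paths in self.targets.items():
            if not paths:
                raise ValueError(f"drug {drug!r} has an empty target set")


def _edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair: lexicographically smaller node first."""
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid edge")
    return (a, b) if a < b else (b, a)


@dataclass
class GeneNetwork:
    """Undirected gene co-expression network.

    Edge attributes: ``r`` (Pearson correlation), ``p_raw`` (two-sided
    p-value), ``q_fdr`` (Benjamini–Hochberg adjusted p).  Isolated genes are
    retained as nodes so node counts stay comparable across networks.
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def without_gene(self, gene: str) -> "GeneNetwork":
        if gene not in self.graph:
            raise KeyError(f"gene {gene!r} not in network")
        g = self.graph.copy()
        g.remove_node(gene)
        return GeneNetwork(g)


@dataclass
class PathwayNetwork:
    """Undirected pathway crosstalk network.

    Edge attributes: ``weight`` (mean correlation of contributing gene
    edges), ``n_gene_edges`` (count of contributing gene edges) and, once a
    permutation test has been applied, ``p_perm``.
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, a: str, b: str) -> float:
        return self.graph.edges[_edge_key(a, b)]["weight"]

    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {
            _edge_key(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)
        }


def edge_key(a: str, b: str) -> tuple[str, str]:
    return _edge_key(a, b)
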