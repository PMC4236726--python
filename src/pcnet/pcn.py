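"""Pathway co-expression network: aggregation and permutation significance.

A gene network is generalized to a pathway network by translating every
gene edge into all unordered pairs of distinct pathways containing its two
endpoints; a pathway edge's weight is the arithmetic mean of the
correlations of the gene edges that form it.  Significance comes from a
label-permutation null: group labels of the pooled (focal + matched
background) samples are reshuffled, the full gene→pathway pipeline is
recomputed per replicate, and each pathway edge receives an add-one
empirical p-value on ``|weight|``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import numpy as np

from .containers import (
    ExpressionMatrix,
    GeneNetwork,
    PathwayAnnotation,
    PathwayNetwork,
    SampleGrouping,
    edge_key,
)
from .gcn import gcn_from_expression
from .netstats import network_features

__all__ = [
    "PipelineParams",
    "NullEnsemble",
    "aggregate_pathway_edges",
    "permutation_null",
    "edge_significance",
    "feature_significance",
    "save_null",
    "load_null",
]


@dataclass(frozen=True)
class PipelineParams:
    """Knobs shared by the observed pipeline and every null replicate."""

    alpha_gcn: float = 0.05
    r_threshold: Optional[float] = 0.5
    alpha_pcn: float = 0.05
    permutations: int = 150

    def to_dict(self) -> dict:
        return {
            "alpha_gcn": self.alpha_gcn,
            "r_threshold": self.r_threshold,
            "alpha_pcn": self.alpha_pcn,
            "permutations": self.permutations,
        }


PairWeights = dict[tuple[str, str], float]


@dataclass
class NullEnsemble:
    """Permutation replicates of pathway-edge weights.

    Each replicate fixes the focal-group size at ``m``, draws pseudo-focal
    samples without replacement from the pooled matrix, and re-runs the
    gene→pathway pipeline.  A pathway pair absent from a replicate's network
    is scored as weight 0.  ``pooled``/``annotation`` are retained (when the
    ensemble is built in memory) so downstream gene-deletion analyses can
    re-run the identical permutations on a reduced gene set.
    """

    R: int
    m: int
    seed: int
    label_assignments: list[list[str]]
    null_weights: list[PairWeights]
    null_features: list[dict[str, float]] = field(default_factory=list)
    params: PipelineParams = field(default_factory=PipelineParams)
    pooled: Optional[ExpressionMatrix] = None
    annotation: Optional[PathwayAnnotation] = None

    def weights_for(self, pair: tuple[str, str]) -> np.ndarray:
        """Per-replicate null weights for one pathway pair (0 when absent)."""
        key = edge_key(*pair)
        return np.array([w.get(key, 0.0) for w in self.null_weights])


def aggregate_pathway_edges(
    gcn: GeneNetwork, annotation: PathwayAnnotation
) -> PathwayNetwork:
    """Collapse gene edges onto pathway pairs (weights only, no p-values).

    For a gene edge ``(g1, g2, r)`` the contributed pairs are every
    unordered ``{P, Q}``, ``P ≠ Q``, with ``P`` containing one endpoint and
    ``Q`` the other, deduplicated within the edge; ``weight(P, Q)`` is the
    mean ``r`` over contributing edges.  Unannotated genes contribute
    nothing.  Nodes are all pathways touched by at least one network gene.
    """
    memb = annotation.gene_pathways
    nodes: set[str] = set()
    any_annotated = False
    for g in gcn.graph.nodes:
        ps = memb.get(g)
        if ps:
            any_annotated = True
            nodes.update(ps)
    if not any_annotated:
        raise ValueError("no gene of the network carries a pathway annotation")
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for g1, g2, r in gcn.graph.edges.data("r"):
        a = memb.get(g1)
        b = memb.get(g2)
        if not a or not b:
            continue
        if len(a) == 1 and len(b) == 1:
            p, q = a[0], b[0]
            if p == q:
                continue
            key = (p, q) if p < q else (q, p)
            sums[key] = sums.get(key, 0.0) + r
            counts[key] = counts.get(key, 0) + 1
        else:
            pairs = set()
            for p in a:
                for q in b:
                    if p != q:
                        pairs.add((p, q) if p < q else (q, p))
            for key in pairs:
                sums[key] = sums.get(key, 0.0) + r
                counts[key] = counts.get(key, 0) + 1
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for key, s in sums.items():
        n = counts[key]
        g.add_edge(key[0], key[1], weight=s / n, n_gene_edges=n, p_perm=None)
    return PathwayNetwork(g)


def _replicate_rng(seed: int, r: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))


def permutation_null(
    pooled: ExpressionMatrix,
    grouping: SampleGrouping,
    m: int,
    annotation: PathwayAnnotation,
    params: PipelineParams = PipelineParams(),
    R: Optional[int] = None,
    seed: int = 0,
    record_features: bool = True,
) -> NullEnsemble:
    """Build the label-permutation null ensemble.

    ``pooled`` holds the focal group plus its matched background group;
    each of ``R`` replicates relabels ``m`` samples (drawn without
    replacement, reproducibly from ``(seed, replicate)``) as pseudo-focal
    and recomputes the full pipeline with the same parameters and gene
    list.
    """
    if R is None:
        R = params.permutations
    if R < 1:
        raise ValueError("need at least one permutation replicate")
    if m > pooled.n_samples:
        raise ValueError(
            f"focal group size m={m} exceeds pooled sample count {pooled.n_samples}"
        )
    if m < 3:
        raise ValueError("focal group size must be ≥ 3")
    grouping.validate_against(pooled)
    assignments: list[list[str]] = []
    weights: list[PairWeights] = []
    features: list[dict[str, float]] = []
    for rep in range(R):
        rng = _replicate_rng(seed, rep)
        idx = rng.choice(pooled.n_samples, size=m, replace=False)
        idx.sort()
        labels = [pooled.sample_ids[i] for i in idx]
        assignments.append(labels)
        g = gcn_from_expression(
            pooled,
            sample_subset=labels,
            alpha=params.alpha_gcn,
            r_threshold=params.r_threshold,
        )
        pn = aggregate_pathway_edges(g, annotation)
        weights.append(pn.edge_weights())
        if record_features:
            features.append(network_features(pn).scalars())
    return NullEnsemble(
        R=R,
        m=m,
        seed=seed,
        label_assignments=assignments,
        null_weights=weights,
        null_features=features,
        params=params,
        pooled=pooled,
        annotation=annotation,
    )


def rerun_null_weights(
    null: NullEnsemble,
    pooled: Optional[ExpressionMatrix] = None,
    drop_genes: Optional[set[str]] = None,
) -> list[PairWeights]:
    """Re-run the stored permutations, optionally on a reduced gene set.

    Reusing the recorded label assignments keeps before/after p-values
    comparable: a change can only come from the removed genes, not from
    fresh Monte-Carlo noise.
    """
    pooled = pooled if pooled is not None else null.pooled
    if pooled is None:
        raise ValueError(
            "this ensemble carries no pooled expression matrix; pass one explicitly"
        )
    if null.annotation is None:
        raise ValueError("this ensemble carries no annotation")
    if drop_genes:
        keep = [g for g in pooled.gene_ids if g not in drop_genes]
        pooled = pooled.subset_genes(keep)
    out: list[PairWeights] = []
    for labels in null.label_assignments:
        g = gcn_from_expression(
            pooled,
            sample_subset=labels,
            alpha=null.params.alpha_gcn,
            r_threshold=null.params.r_threshold,
        )
        out.append(aggregate_pathway_edges(g, null.annotation).edge_weights())
    return out


def empirical_p(null_values: np.ndarray, observed: float, two_sided_abs: bool = True) -> float:
    """Add-one empirical p-value: ``(1 + #{null ≥ obs}) / (R + 1)``.

    With ``two_sided_abs`` the comparison is on absolute values, matching
    the two-sided treatment of crosstalk weights (positive and negative
    crosstalk are both of interest).
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null vector")
    if two_sided_abs:
        count = int(np.sum(np.abs(null_values) >= abs(observed)))
    else:
        count = int(np.sum(null_values >= observed))
    return (1 + count) / (null_values.size + 1)


def edge_significance(
    observed: PathwayNetwork,
    null: NullEnsemble,
    alpha_pcn: float = 0.05,
    null_weights: Optional[list[PairWeights]] = None,
) -> PathwayNetwork:
    """Attach permutation p-values and retain edges with ``p < alpha_pcn``.

    ``p_perm(P,Q) = (1 + #{replicates: |null weight| ≥ |observed weight|})
    / (R + 1)``; the comparison pool records 0 for replicates in which the
    pair formed no edge.  Isolated pathways stay as nodes.
    """
    weights = null_weights if null_weights is not None else null.null_weights
    known: Optional[set[str]] = None
    if null.annotation is not None:
        known = set(null.annotation.pathways)
    g = nx.Graph()
    g.add_nodes_from(observed.graph.nodes)
    for u, v, d in observed.graph.edges(data=True):
        key = edge_key(u, v)
        if known is not None and (key[0] not in known or key[1] not in known):
            raise ValueError(
                f"observed pathway edge {key} has no counterpart in the null "
                "ensemble's annotation"
            )
        nulls = np.array([w.get(key, 0.0) for w in weights])
        p = empirical_p(nulls, d["weight"])
        if p < alpha_pcn:
            g.add_edge(
                key[0],
                key[1],
                weight=d["weight"],
                n_gene_edges=d["n_gene_edges"],
                p_perm=p,
            )
    return PathwayNetwork(g)


def feature_significance(
    feature_values_null, feature_observed: float
) -> tuple[float, float, float]:
    """Upper, lower, and two-sided empirical p for one network feature."""
    nulls = np.asarray(feature_values_null, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null vector")
    p_upper = (1 + int(np.sum(nulls >= feature_observed))) / (nulls.size + 1)
    p_lower = (1 + int(np.sum(nulls <= feature_observed))) / (nulls.size + 1)
    return p_upper, p_lower, min(1.0, 2.0 * min(p_upper, p_lower))


def save_null(
    null: NullEnsemble, weights_path: Union[str, Path], meta_path: Union[str, Path]
) -> None:
    """Persist replicate × pathway-pair weights (TSV) plus a JSON sidecar.

    The sidecar records the seed, m, parameters, label assignments and
    per-replicate features, so significance can be recomputed without
    re-running the permutations.
    """
    pairs = sorted({k for w in null.null_weights for k in w})
    with Path(weights_path).open("w") as fh:
        fh.write("pathway_a\tpathway_b\t" + "\t".join(f"rep_{i}" for i in range(null.R)) + "\n")
        for a, b in pairs:
            vals = "\t".join("%.6f" % w.get((a, b), 0.0) for w in null.null_weights)
            fh.write(f"{a}\t{b}\t{vals}\n")
    meta = {
        "R": null.R,
        "m": null.m,
        "seed": null.seed,
        "params": null.params.to_dict(),
        "label_assignments": null.label_assignments,
        "null_features": null.null_features,
    }
    with Path(meta_path).open("w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_null(
    weights_path: Union[str, Path], meta_path: Union[str, Path]
) -> NullEnsemble:
    """Reload a persisted ensemble (weights + labels; no expression data)."""
    with Path(meta_path).open() as fh:
        meta = json.load(fh)
    params = PipelineParams(**meta["params"])
    R = meta["R"]
    weights: list[PairWeights] = [dict() for _ in range(R)]
    with Path(weights_path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != R + 2:
            raise ValueError("null weight table does not match the recorded R")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            a, b = parts[0], parts[1]
            for i, cell in enumerate(parts[2:]):
                w = float(cell)
                if w != 0.0:
                    weights[i][(a, b)] = w
    return NullEnsemble(
        R=R,
        m=meta["m"],
        seed=meta["seed"],
        label_assignments=meta["label_assignments"],
        null_weights=weights,
        null_features=meta.get("null_features", []),
        params=params,
    )
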