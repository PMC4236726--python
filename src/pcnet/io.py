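"""Readers and writers for every external format the pipeline touches.

Formats: tab-separated expression tables (genes as rows, samples as
columns), two-column TSV sample groupings, GMT gene sets, two-column TSV
pathway→category and drug→pathway maps, and network exports as TSV edge
lists or GraphML (loadable by Cytoscape).  All validation is strict:
duplicate or malformed entries raise with the offending coordinate.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    DrugTargetMap,
    ExpressionMatrix,
    GeneNetwork,
    PathwayAnnotation,
    PathwayNetwork,
    SampleGrouping,
    edge_key,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_grouping",
    "write_grouping",
    "read_gene_sets",
    "write_gene_sets",
    "read_drug_targets",
    "write_drug_targets",
    "read_gene_list",
    "write_network",
    "read_network",
]

#: decimal digits used for every serialized weight / statistic
FLOAT_DIGITS = 6
_FMT = f"%.{FLOAT_DIGITS}f"

GENE_EDGE_COLUMNS = ("node_a", "node_b", "r", "p_raw", "q_fdr")
PATHWAY_EDGE_COLUMNS = ("node_a", "node_b", "weight", "n_gene_edges", "p_perm")


def read_expression(path: Union[str, Path]) -> ExpressionMatrix:
    """Read a genes × samples TSV (first row sample ids, first column gene ids)."""
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            gene = row[0]
            body = row[1:]
            if len(body) != len(sample_ids):
                raise ValueError(
                    f"{path}:{lineno}: gene {gene!r} has {len(body)} values, "
                    f"expected {len(sample_ids)}"
                )
            vals = []
            for j, cell in enumerate(body):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} at gene "
                        f"{gene!r}, sample {sample_ids[j]!r}"
                    ) from None
                if not np.isfinite(vals[-1]):
                    raise ValueError(
                        f"{path}:{lineno}: non-finite cell {cell!r} at gene "
                        f"{gene!r}, sample {sample_ids[j]!r}"
                    )
            gene_ids.append(gene)
            rows.append(vals)
    return ExpressionMatrix(np.array(rows, dtype=float), gene_ids, sample_ids)


def write_expression(matrix: ExpressionMatrix, path: Union[str, Path]) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format=_FMT, index_label="gene_id")


def read_grouping(path: Union[str, Path]) -> SampleGrouping:
    """Two-column TSV: sample_id, group label. Header optional but expected."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, group)")
    assignment: dict[str, str] = {}
    for sample, group in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        if sample in assignment:
            raise ValueError(f"{path}: duplicate sample id {sample!r}")
        assignment[sample] = group
    return SampleGrouping(assignment)


def write_grouping(grouping: SampleGrouping, path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in grouping.assignment.items():
            fh.write(f"{s}\t{g}\n")


def read_gene_sets(
    gmt_path: Union[str, Path], category_path: Union[str, Path, None] = None
) -> PathwayAnnotation:
    """Parse a GMT gene-set file plus an optional pathway→category TSV.

    GMT lines are ``name<TAB>description<TAB>gene1<TAB>gene2...``; pathways
    absent from the category file are labelled ``uncategorized``.  Line order
    is irrelevant.
    """
    pathway_genes: dict[str, set[str]] = {}
    gmt_path = Path(gmt_path)
    with gmt_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{gmt_path}:{lineno}: pathway {parts[0]!r} has no member genes"
                )
            name = parts[0]
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ValueError(
                    f"{gmt_path}:{lineno}: pathway {name!r} has no member genes"
                )
            if name in pathway_genes:
                raise ValueError(f"{gmt_path}:{lineno}: duplicate pathway id {name!r}")
            pathway_genes[name] = genes
    categories: dict[str, str] = {}
    if category_path is not None:
        frame = pd.read_csv(category_path, sep="\t", dtype=str)
        for pathway, category in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
            categories[pathway] = category
    return PathwayAnnotation(pathway_genes, categories)


def write_gene_sets(
    annotation: PathwayAnnotation,
    gmt_path: Union[str, Path],
    category_path: Union[str, Path, None] = None,
) -> None:
    with Path(gmt_path).open("w") as fh:
        for p in sorted(annotation.pathway_genes):
            genes = "\t".join(sorted(annotation.pathway_genes[p]))
            fh.write(f"{p}\tna\t{genes}\n")
    if category_path is not None:
        with Path(category_path).open("w") as fh:
            fh.write("pathway_id\tcategory\n")
            for p in sorted(annotation.pathway_genes):
                fh.write(f"{p}\t{annotation.category(p)}\n")


def read_drug_targets(path: Union[str, Path]) -> DrugTargetMap:
    """Two-column TSV (drug, pathway_id); one row per drug–pathway pair."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (drug, pathway_id)")
    targets: dict[str, set[str]] = {}
    for drug, pathway in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        targets.setdefault(drug, set()).add(pathway)
    return DrugTargetMap(targets)


def write_drug_targets(drug_map: DrugTargetMap, path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        fh.write("drug\tpathway_id\n")
        for drug in sorted(drug_map.targets):
            for pathway in sorted(drug_map.targets[drug]):
                fh.write(f"{drug}\t{pathway}\n")


def read_gene_list(path: Union[str, Path]) -> list[str]:
    """One gene id per line (a signature list)."""
    genes: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            g = line.strip()
            if g:
                genes.append(g)
    if not genes:
        raise ValueError(f"{path}: empty gene list")
    return genes


def _is_pathway_network(network) -> bool:
    return isinstance(network, PathwayNetwork)


def write_network(
    network: Union[GeneNetwork, PathwayNetwork],
    path: Union[str, Path],
    format: str = "edge_list",
) -> None:
    """Serialize a network as a TSV edge list or GraphML.

    Edge lists store each unordered pair once (smaller node first), rows
    sorted, floats at 6 decimals; reading an edge list back reproduces the
    edge set and weights bit-for-bit at that precision.
    """
    path = Path(path)
    if format == "graphml":
        g = network.graph.copy()
        for _, _, d in g.edges(data=True):
            for k, v in list(d.items()):
                if v is None:
                    del d[k]
        nx.write_graphml(g, path)
        return
    if format != "edge_list":
        raise ValueError(f"unknown network format {format!r}")
    cols = PATHWAY_EDGE_COLUMNS if _is_pathway_network(network) else GENE_EDGE_COLUMNS
    rows = []
    for u, v, d in network.graph.edges(data=True):
        a, b = edge_key(u, v)
        if _is_pathway_network(network):
            p = d.get("p_perm")
            rows.append(
                (
                    a,
                    b,
                    _FMT % d["weight"],
                    str(int(d["n_gene_edges"])),
                    "NA" if p is None else _FMT % p,
                )
            )
        else:
            rows.append(
                (a, b, _FMT % d["r"], _FMT % d["p_raw"], _FMT % d["q_fdr"])
            )
    rows.sort()
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_network(path: Union[str, Path]) -> Union[GeneNetwork, PathwayNetwork]:
    """Read a TSV edge list written by :func:`write_network`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) == GENE_EDGE_COLUMNS:
            kind = "gene"
        elif tuple(header) == PATHWAY_EDGE_COLUMNS:
            kind = "pathway"
        else:
            raise ValueError(f"{path}: unrecognized edge-list header {header}")
        g = nx.Graph()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            a, b = parts[0], parts[1]
            if kind == "gene":
                g.add_edge(
                    a, b, r=float(parts[2]), p_raw=float(parts[3]), q_fdr=float(parts[4])
                )
            else:
                p = None if parts[4] == "NA" else float(parts[4])
                g.add_edge(
                    a, b, weight=float(parts[2]), n_gene_edges=int(parts[3]), p_perm=p
                )
    return GeneNetwork(g) if kind == "gene" else PathwayNetwork(g)
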