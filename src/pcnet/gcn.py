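"""Gene co-expression network construction.

Edges are pairwise Pearson correlations tested with the exact t transform
(two-sided, n−2 degrees of freedom), adjusted by Benjamini–Hochberg over
all distinct gene pairs, and kept when the adjusted value falls below
``alpha`` and, optionally, ``|r|`` reaches a magnitude threshold.  Isolated
genes stay in the network as nodes.
"""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx
import numpy as np
from scipy import stats

from .containers import ExpressionMatrix, GeneNetwork

__all__ = ["pearson_all_pairs", "bh_fdr", "build_gcn", "gcn_from_expression"]


def pearson_all_pairs(
    matrix: ExpressionMatrix, sample_subset: Optional[Iterable[str]] = None
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p over a sample subset.

    Returns the symmetric correlation matrix (unit diagonal) and the matrix
    of two-sided p-values from ``t = r·sqrt((n−2)/(1−r²))`` with ``n−2``
    degrees of freedom (diagonal p set to 0).
    """
    sub = matrix if sample_subset is None else matrix.subset_samples(sample_subset)
    n = sub.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    sd = sub.values.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance gene over the sample subset: {sub.gene_ids[zero[0]]!r} "
            "(filter constant genes before correlation)"
        )
    r = np.corrcoef(sub.values)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(p)] = 0.0  # |r| == 1 → t infinite → p = 0
    np.fill_diagonal(p, 0.0)
    p = np.minimum(p, 1.0)
    return r, p


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j ≥ i} p_(j)·m/j`` over the ascending-sorted p-values,
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_fdr expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def build_gcn(
    r: np.ndarray,
    p: np.ndarray,
    gene_ids: list[str],
    alpha: float = 0.05,
    r_threshold: Optional[float] = 0.5,
) -> GeneNetwork:
    """Assemble the network: FDR over all distinct pairs, then thresholds.

    An edge is kept iff its BH-adjusted p is below ``alpha`` and (when a
    threshold is given) ``|r| ≥ r_threshold``; the two criteria are
    conjunctive so their order is irrelevant.  All genes become nodes.
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    n = len(gene_ids)
    if r.shape != (n, n) or p.shape != (n, n):
        raise ValueError("r and p must be square matrices matching gene_ids")
    iu, ju = np.triu_indices(n, k=1)
    q_flat = bh_fdr(p[iu, ju])
    r_flat = r[iu, ju]
    keep = q_flat < alpha
    if r_threshold:
        keep &= np.abs(r_flat) >= r_threshold
    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    p_flat = p[iu, ju]
    for k in np.flatnonzero(keep):
        g.add_edge(
            gene_ids[iu[k]],
            gene_ids[ju[k]],
            r=float(r_flat[k]),
            p_raw=float(p_flat[k]),
            q_fdr=float(q_flat[k]),
        )
    return GeneNetwork(g)


def gcn_from_expression(
    matrix: ExpressionMatrix,
    sample_subset: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
    r_threshold: Optional[float] = 0.5,
) -> GeneNetwork:
    """Convenience: correlations + FDR + assembly in one call."""
    sub = matrix if sample_subset is None else matrix.subset_samples(sample_subset)
    r, p = pearson_all_pairs(sub)
    return build_gcn(r, p, list(sub.gene_ids), alpha=alpha, r_threshold=r_threshold)
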