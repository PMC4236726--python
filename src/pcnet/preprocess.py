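"""Quantile normalization, low-signal/low-variance gene filters and
signature subsetting.

The filters mirror a common microarray preprocessing recipe: drop genes
whose mean absolute expression sits in the lowest decile of the data set
and genes whose across-sample variance sits in the lowest decile; the two
criteria are combined by union (a config switch allows intersection).
Filtering is applied after quantile normalization so the variance criterion
is scale-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .containers import ExpressionMatrix

__all__ = ["FilterReport", "quantile_normalize", "filter_low_signal", "subset_to_signature"]

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Which genes each filter removed, and the surviving gene list."""

    removed_low_abs: set[str]
    removed_low_var: set[str]
    kept: list[str]

    def write(self, path: Union[str, Path]) -> None:
        with Path(path).open("w") as fh:
            fh.write("gene_id\treason\n")
            for g in sorted(self.removed_low_abs):
                fh.write(f"{g}\tlow_abs\n")
            for g in sorted(self.removed_low_var):
                fh.write(f"{g}\tlow_var\n")
            for g in self.kept:
                fh.write(f"{g}\tkept\n")


def quantile_normalize(matrix: ExpressionMatrix, ties: str = "average") -> ExpressionMatrix:
    """Force every sample column onto one reference distribution.

    The reference is the per-rank mean of the sorted columns.  Two tie
    dialects are offered:

    ``"average"`` (default)
        Tied values within a column all receive the mean of the reference
        values at their tied ranks — the convention most array pipelines
        use.  With ties present, columns then share the reference
        distribution only up to tie-averaging.
    ``"rank"``
        Ties are broken by stable input order and each value receives the
        reference value at its rank.  Every column's sorted vector is then
        exactly the reference, and the transform is exactly idempotent,
        ties included.
    """
    if ties not in ("average", "rank"):
        raise ValueError(f"unknown tie dialect {ties!r}")
    x = matrix.values
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    order = np.argsort(x, axis=0, kind="stable")
    sorted_cols = np.sort(x, axis=0)
    if np.array_equal(sorted_cols, sorted_cols[:, [0]].repeat(x.shape[1], axis=1)):
        # already a common distribution: averaging identical columns would
        # perturb by one ulp, so use the column itself (exact fixed point)
        reference = sorted_cols[:, 0]
    else:
        reference = sorted_cols.mean(axis=1)
    out = np.empty_like(x)
    n = x.shape[0]
    ranks = np.empty(n, dtype=int)
    for j in range(x.shape[1]):
        col_order = order[:, j]
        ranks[col_order] = np.arange(n)
        normalized = reference[ranks]
        if ties == "average":
            col = x[:, j]
            sorted_col = col[col_order]
            # group identical consecutive values in sorted order; average the
            # reference over each tied run
            boundary = np.empty(n, dtype=bool)
            boundary[0] = True
            boundary[1:] = sorted_col[1:] != sorted_col[:-1]
            group = np.cumsum(boundary) - 1
            n_groups = group[-1] + 1
            sums = np.bincount(group, weights=reference, minlength=n_groups)
            counts = np.bincount(group, minlength=n_groups)
            means = sums / counts
            normalized = np.empty(n)
            normalized[col_order] = means[group]
        out[:, j] = normalized
    return ExpressionMatrix(out, list(matrix.gene_ids), list(matrix.sample_ids))


def filter_low_signal(
    matrix: ExpressionMatrix,
    abs_percentile: float = 0.10,
    var_percentile: float = 0.10,
    combine: str = "union",
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes with low mean absolute expression and/or low variance.

    A gene is flagged by a criterion when its statistic falls *strictly
    below* the given quantile (inclusive linear-interpolation convention) of
    the per-gene statistics; a gene sitting exactly on the boundary is kept.
    ``combine`` is ``"union"`` (default) or ``"intersection"``.
    """
    if not (0 <= abs_percentile < 1) or not (0 <= var_percentile < 1):
        raise ValueError("percentiles must lie in [0, 1)")
    if combine not in ("union", "intersection"):
        raise ValueError(f"unknown combine rule {combine!r}")
    means = np.abs(matrix.values).mean(axis=1)
    variances = matrix.values.var(axis=1, ddof=1)
    abs_cut = np.quantile(means, abs_percentile, method="linear")
    var_cut = np.quantile(variances, var_percentile, method="linear")
    low_abs = means < abs_cut
    low_var = variances < var_cut
    removed = (low_abs | low_var) if combine == "union" else (low_abs & low_var)
    kept_ids = [g for g, r in zip(matrix.gene_ids, removed) if not r]
    if not kept_ids:
        raise ValueError("all genes removed by the low-signal filters")
    report = FilterReport(
        removed_low_abs={g for g, f in zip(matrix.gene_ids, low_abs) if f},
        removed_low_var={g for g, f in zip(matrix.gene_ids, low_var) if f},
        kept=kept_ids,
    )
    if len(kept_ids) < 2:
        raise ValueError("fewer than 2 genes survive the low-signal filters")
    return matrix.subset_genes(kept_ids), report


def subset_to_signature(
    matrix: ExpressionMatrix, signature: Iterable[str]
) -> ExpressionMatrix:
    """Restrict rows to a signature gene list, preserving matrix order.

    Signature genes absent from the matrix are logged as warnings, not
    errors; an empty intersection is an error.
    """
    signature = list(signature)
    if not signature:
        raise ValueError("empty signature")
    wanted = set(signature)
    present = [g for g in matrix.gene_ids if g in wanted]
    missing = sorted(wanted - set(present))
    if missing:
        log.warning("signature genes absent from matrix: %s", ", ".join(missing))
    if not present:
        raise ValueError("no signature gene found in the expression matrix")
    if len(present) < 2:
        raise ValueError("signature intersection has fewer than 2 genes")
    return matrix.subset_genes(present)
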