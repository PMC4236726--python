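"""End-to-end orchestration: expression table in, crosstalk artifacts out.

Stages run in a fixed order — normalize, (optional) signature subset,
low-signal filters, gene network on the focal group, pathway aggregation,
permutation null on the pooled focal+background samples, edge and feature
significance, circle inventories, category circles and (optionally) drug
intervention comparison — each persisting its output so any stage can be
re-loaded and re-run independently.  A single master seed drives every
source of randomness; identical config + seed reproduces every artifact
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from . import io as pio
from .containers import DrugTargetMap, PathwayAnnotation
from .gcn import gcn_from_expression
from .intervention import compare_target_sets
from .netstats import enumerate_circles, network_features, top_hubs
from .pcn import (
    PipelineParams,
    aggregate_pathway_edges,
    edge_significance,
    feature_significance,
    permutation_null,
    save_null,
)
from .preprocess import filter_low_signal, quantile_normalize, subset_to_signature
from .redundancy import categorize_circles, write_category_circles

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)

_REQUIRED = ("expression", "groups", "gmt", "focal_group", "background_group")


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run."""

    expression: Path
    groups: Path
    gmt: Path
    focal_group: str
    background_group: str
    categories: Optional[Path] = None
    drugs: Optional[Path] = None
    signature: Optional[Path] = None
    alpha_gcn: float = 0.05
    r_threshold: Optional[float] = 0.5
    alpha_pcn: float = 0.05
    permutations: int = 150
    abs_percentile: float = 0.10
    var_percentile: float = 0.10
    filter_combine: str = "union"
    normalize: bool = True
    hub_k: int = 10
    seed: int = 0
    out: Path = Path("pcn_out")

    def __post_init__(self) -> None:
        for name in ("expression", "groups", "gmt", "categories", "drugs", "signature"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        self.out = Path(self.out)
        for prob in (self.alpha_gcn, self.alpha_pcn):
            if not (0 < prob):
                raise ValueError("alpha values must be positive")
        if self.permutations < 1:
            raise ValueError("permutations must be ≥ 1")
        for name in ("expression", "groups", "gmt", "categories", "drugs", "signature"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config field {name!r}: no such file {value}")

    def params(self) -> PipelineParams:
        return PipelineParams(
            alpha_gcn=self.alpha_gcn,
            r_threshold=self.r_threshold,
            alpha_pcn=self.alpha_pcn,
            permutations=self.permutations,
        )


def load_config(path: Union[str, Path], **overrides) -> RunConfig:
    """Read a YAML key-value config; keyword overrides win over the file."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a key-value document")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    missing = [k for k in _REQUIRED if not raw.get(k)]
    if missing:
        raise ValueError(f"{path}: missing required config field(s): {', '.join(missing)}")
    base = Path(path).parent
    for name in ("expression", "groups", "gmt", "categories", "drugs", "signature"):
        if raw.get(name) is not None and not Path(raw[name]).is_absolute():
            raw[name] = base / raw[name]
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the artifact directory."""
    out = config.out
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage(name: str):
        log.info("stage: %s", name)
        return name

    name = stage("read inputs")
    try:
        matrix = pio.read_expression(config.expression)
        grouping = pio.read_grouping(config.groups)
        annotation: PathwayAnnotation = pio.read_gene_sets(config.gmt, config.categories)
        drug_map: Optional[DrugTargetMap] = (
            pio.read_drug_targets(config.drugs) if config.drugs else None
        )
        signature = pio.read_gene_list(config.signature) if config.signature else None
        grouping.validate_against(matrix)
        focal_samples = grouping.samples(config.focal_group)
        background_samples = grouping.samples(config.background_group)
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    name = stage("preprocess")
    try:
        normalized = quantile_normalize(matrix) if config.normalize else matrix
        if signature:
            normalized = subset_to_signature(normalized, signature)
        filtered, report = filter_low_signal(
            normalized,
            abs_percentile=config.abs_percentile,
            var_percentile=config.var_percentile,
            combine=config.filter_combine,
        )
        pio.write_expression(normalized, out / "normalized.tsv")
        report.write(out / "filter_report.tsv")
        counts["genes_input"] = matrix.n_genes
        counts["genes_kept"] = filtered.n_genes
        log.info("genes kept after filters: %d / %d", filtered.n_genes, matrix.n_genes)
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    name = stage("gene network")
    try:
        gene_net = gcn_from_expression(
            filtered,
            sample_subset=focal_samples,
            alpha=config.alpha_gcn,
            r_threshold=config.r_threshold,
        )
        pio.write_network(gene_net, out / "gcn_edges.tsv")
        counts["gcn_nodes"] = gene_net.n_nodes
        counts["gcn_edges"] = gene_net.n_edges
        log.info("gene network: %d nodes, %d edges", gene_net.n_nodes, gene_net.n_edges)
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    name = stage("pathway network")
    try:
        aggregated = aggregate_pathway_edges(gene_net, annotation)
        pooled = filtered.subset_samples(focal_samples + background_samples)
        null = permutation_null(
            pooled,
            grouping,
            m=len(focal_samples),
            annotation=annotation,
            params=config.params(),
            seed=config.seed,
        )
        save_null(null, out / "null_weights.tsv", out / "null_meta.json")
        pathway_net = edge_significance(aggregated, null, config.alpha_pcn)
        pio.write_network(pathway_net, out / "pcn_edges.tsv")
        pio.write_network(pathway_net, out / "pcn.graphml", format="graphml")
        counts["pcn_nodes"] = pathway_net.n_nodes
        counts["pcn_edges"] = pathway_net.n_edges
        log.info(
            "pathway network: %d nodes, %d significant edges",
            pathway_net.n_nodes,
            pathway_net.n_edges,
        )
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    name = stage("network features")
    try:
        bundle = network_features(pathway_net)
        observed = bundle.scalars()
        with (out / "features.tsv").open("w") as fh:
            fh.write("feature\tobserved\tnull_mean\tp_upper\tp_lower\tp_two_sided\n")
            for key in sorted(observed):
                nulls = [f[key] for f in null.null_features if key in f]
                if nulls:
                    p_up, p_lo, p_two = feature_significance(nulls, observed[key])
                    null_mean = sum(nulls) / len(nulls)
                    fh.write(
                        f"{key}\t{observed[key]:.6f}\t{null_mean:.6f}"
                        f"\t{p_up:.6f}\t{p_lo:.6f}\t{p_two:.6f}\n"
                    )
                else:
                    fh.write(f"{key}\t{observed[key]:.6f}\tNA\tNA\tNA\tNA\n")
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    name = stage("circles")
    try:
        circles3 = enumerate_circles(pathway_net, 3)
        circles4 = enumerate_circles(pathway_net, 4)
        circles3.write(out / "circles3.tsv")
        circles4.write(out / "circles4.tsv")
        write_category_circles(
            categorize_circles(circles3, annotation), out / "category_circles.tsv"
        )
        counts["circles3"] = len(circles3)
        counts["circles4"] = len(circles4)
        log.info("circles: %d triangles, %d 4-node", len(circles3), len(circles4))
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    if drug_map is not None and pathway_net.n_edges > 0:
        name = stage("intervention")
        try:
            named: dict[str, set[str]] = {
                drug: targets for drug, targets in sorted(drug_map.targets.items())
            }
            named["top_hubs"] = set(top_hubs(pathway_net, config.hub_k))
            usable = {
                n: t for n, t in named.items() if t & set(pathway_net.graph.nodes)
            }
            if len(usable) >= 2:
                table = compare_target_sets(pathway_net, usable, hub_k=config.hub_k)
                table.to_csv(out / "intervention.tsv", sep="\t", float_format="%.6f")
                counts["intervention_sets"] = len(usable)
            else:
                log.warning("fewer than 2 usable target sets; intervention skipped")
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    manifest = {
        "pcnet_version": __version__,
        "seed": config.seed,
        "focal_group": config.focal_group,
        "background_group": config.background_group,
        "parameters": {
            **config.params().to_dict(),
            "abs_percentile": config.abs_percentile,
            "var_percentile": config.var_percentile,
            "filter_combine": config.filter_combine,
            "normalize": config.normalize,
            "hub_k": config.hub_k,
        },
        "inputs": {
            name: str(getattr(config, name))
            for name in ("expression", "groups", "gmt", "categories", "drugs", "signature")
            if getattr(config, name) is not None
        },
        "counts": counts,
    }
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
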