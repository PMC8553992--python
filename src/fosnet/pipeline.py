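"""End-to-end orchestration: read -> screen -> correlate -> cluster ->
threshold -> metrics -> export.

Every condition is analyzed fully independently (its own correlation
matrix, dendrogram, module partition, signed graph and node metrics); the
group screen is the only study-level stage. All artifacts are plain text
and a pure function of (input bytes, config, seed), so re-running a
pipeline reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import (
    LinkageTree,
    ModulePartition,
    count_isolates,
    modules_from_correlation,
)
from .coactivity import CorrelationMatrix, correlation_matrix, heatmap_export
from .graph import NodeMetrics, SignedGraph, export_graph, node_metrics_table, threshold_edges
from .io import read_long
from .regions import RegionSet
from .screen import RegionScreen, screen_regions
from .synthetic import StudyDataset


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; the defaults are the analysis' canonical parameters:
    edge threshold |R| > 0.5, dendrogram cut at half the tree height,
    complete linkage, alpha 0.05."""

    input_path: str = ""
    output_dir: str = "fosnet_out"
    condition_column: str = "condition"
    edge_threshold: float = 0.5
    cut_fraction: float = 0.5
    linkage_method: str = "complete"
    alpha: float = 0.05
    min_pairs: int = 5
    seed: int = 0
    export_formats: tuple[str, ...] = ("graphml", "gexf")
    plots: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "export_formats" in raw:
            raw["export_formats"] = tuple(raw["export_formats"])
        return cls(**raw)


@dataclass(frozen=True)
class ConditionNetwork:
    """All per-condition artifacts."""

    condition: str
    correlation: CorrelationMatrix
    tree: LinkageTree
    partition: ModulePartition
    graph: SignedGraph
    metrics: NodeMetrics
    n_isolates: int


@dataclass(frozen=True)
class NetworkReport:
    config: PipelineConfig
    screen: RegionScreen
    networks: dict[str, ConditionNetwork] = field(default_factory=dict)


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_")


def _complete_submatrix(cm: CorrelationMatrix) -> CorrelationMatrix:
    """Drop regions until no missing correlations remain.

    Greedy: repeatedly remove the region with the most missing pairs.
    """
    R = cm.R.copy()
    n = cm.n_used.copy()
    dropped = []
    while R.isna().to_numpy().any():
        worst = R.isna().sum().idxmax()
        dropped.append(worst)
        R = R.drop(index=worst, columns=worst)
        n = n.drop(index=worst, columns=worst)
    if dropped:
        warnings.warn(
            f"condition {cm.condition_name!r}: dropped region(s) {dropped} "
            "with missing correlations before clustering"
        )
    return CorrelationMatrix(
        condition_name=cm.condition_name,
        regions=RegionSet(R.columns),
        R=R,
        n_used=n,
    )


def analyze_condition(cm: CorrelationMatrix, config: PipelineConfig) -> ConditionNetwork:
    """Correlation matrix -> modules -> signed graph -> node metrics."""
    cm = _complete_submatrix(cm)
    tree, partition = modules_from_correlation(
        cm, linkage_method=config.linkage_method, cut_fraction=config.cut_fraction
    )
    graph = threshold_edges(cm, threshold=config.edge_threshold)
    metrics = node_metrics_table(graph, partition)
    return ConditionNetwork(
        condition=cm.condition_name,
        correlation=cm,
        tree=tree,
        partition=partition,
        graph=graph,
        metrics=metrics,
        n_isolates=count_isolates(partition),
    )


def run_pipeline(config: PipelineConfig) -> NetworkReport:
    """Execute every stage and write all artifacts to ``config.output_dir``."""
    input_path = Path(config.input_path)
    tables = read_long(input_path)
    for cond in [c for c, t in tables.items() if t.n_subjects < 2]:
        warnings.warn(f"condition {cond!r} has fewer than 2 subjects; skipped")
        del tables[cond]
    if not tables:
        raise ValueError("no analyzable conditions in input")

    region_set = next(iter(tables.values())).region_set
    study = StudyDataset(
        conditions=tables, region_set=region_set, truth={}, seed=config.seed
    )
    screen = screen_regions(study, alpha=config.alpha)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    screen.to_frame().to_csv(out / "region_screen.tsv", sep="\t", index=False)

    networks: dict[str, ConditionNetwork] = {}
    summary_rows = []
    for cond, table in tables.items():
        cm = correlation_matrix(table, min_pairs=config.min_pairs)
        net = analyze_condition(cm, config)
        networks[cond] = net
        slug = _slug(cond)

        net.correlation.R.to_csv(out / f"correlation_{slug}.tsv", sep="\t", index_label="region")
        net.correlation.n_used.to_csv(out / f"n_used_{slug}.tsv", sep="\t", index_label="region")
        net.tree.to_frame().to_csv(out / f"linkage_{slug}.tsv", sep="\t", index_label="merge")
        net.partition.to_frame().to_csv(out / f"partition_{slug}.tsv", sep="\t", index=False)
        net.graph.edge_frame().to_csv(out / f"edges_{slug}.tsv", sep="\t", index=False)
        net.metrics.table.to_csv(out / f"node_metrics_{slug}.tsv", sep="\t", index=False)
        for fmt in config.export_formats:
            suffix = {"graphml": ".graphml", "gexf": ".gexf", "edgelist": ".edges"}[fmt]
            export_graph(net.graph, net.metrics, out / f"network_{slug}{suffix}", fmt=fmt)
        if config.plots:
            heatmap_export(net.correlation, out / f"heatmap_{slug}")

        summary_rows.append(
            {
                "condition": cond,
                "n_subjects": table.n_subjects,
                "n_regions": len(net.correlation.regions),
                "n_modules": net.partition.n_modules,
                "n_isolates": net.n_isolates,
                "n_edges": len(net.graph.edges),
                "n_negative_edges": sum(1 for w in net.graph.edges.values() if w < 0),
            }
        )
    pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t", index=False)

    manifest = {
        "tool": "fosnet",
        "version": __version__,
        "seed": config.seed,
        "input_sha256": hashlib.sha256(input_path.read_bytes()).hexdigest(),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return NetworkReport(config=config, screen=screen, networks=networks)
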