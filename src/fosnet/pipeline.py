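"""End-to-end orchestration: config in, full stage outputs plus manifest out.

The pipeline runs ingest (or the synthetic generator) -> regional screen ->
per-group correlation matrices -> thresholded networks with metrics and MCL
clusters -> null ensembles and threshold sweep -> hub identification and
robustness, writing every stage product under the output directory and a JSON
manifest recording parameters, seeds and SHA-256 hashes of every file.  Reruns
with the same config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hubs import DEFAULT_PRUNE_GRID, compare_hub_sets, hub_robustness
from .ingest import (RegionCountTable, RegionMetadata, ValidationError,
                     aggregate_counts, filter_matched)
from .model import FunctionalNetworkModel, RegionalActivationModel
from .network_metrics import DEFAULT_INFLATION_GRID
from .null_models import DEFAULT_P_GRID, DEFAULT_SWAPS_PER_EDGE, threshold_sweep
from .synthetic import CohortSpec, generate_cohort, planted_truth

log = logging.getLogger("fosnet.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative description of one full analysis run.

    Exactly one input source must be set: ``synthetic`` (kwargs for
    :class:`CohortSpec`, or ``{"blocks": {...}}`` for the canned block
    design), ``raw_records`` (long CSV plus optional ``region_metadata``),
    or ``wide_table`` (an already-aggregated wide CSV).
    """

    out_dir: str = "fosnet_out"
    synthetic: dict | None = None
    raw_records: str | None = None
    region_metadata: str | None = None
    wide_table: str | None = None
    alpha: float = 0.05
    network_p: float = 0.05
    gate_contrasts_on_interaction: bool = True
    fdr: bool = False
    sweep_grid: list[float] = field(default_factory=lambda: list(DEFAULT_P_GRID))
    prune_grid: list[float] = field(default_factory=lambda: list(DEFAULT_PRUNE_GRID))
    inflation_grid: list[float] = field(default_factory=lambda: list(DEFAULT_INFLATION_GRID))
    null_replicates: int = 1000
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE
    sw_random_graphs: int = 100
    sw_random_graphs_null: int = 20
    run_sweep: bool = True
    top_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        sources = [s is not None for s in (self.synthetic, self.raw_records,
                                           self.wide_table)]
        if sum(sources) != 1:
            raise ValidationError(
                "exactly one input source (synthetic | raw_records | wide_table) required")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset covers JSON
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonify(obj):
    """Make config structures JSON-safe (tuple keys -> 'a:b' strings)."""
    if isinstance(obj, dict):
        return {(":".join(map(str, k)) if isinstance(k, tuple) else str(k)):
                _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _group_tag(group: tuple[str, str]) -> str:
    return f"{group[0]}_{group[1]}"


def _load_table(config: PipelineConfig, out: Path, manifest: dict) -> RegionCountTable:
    if config.synthetic is not None:
        params = dict(config.synthetic)
        params.setdefault("seed", config.seed)
        if "blocks" in params:
            block_kwargs = params.pop("blocks")
            block_kwargs.setdefault("seed", params.pop("seed"))
            spec = CohortSpec.with_blocks(**block_kwargs, **params)
        else:
            spec = CohortSpec(**params)
        table = generate_cohort(spec)
        truth = planted_truth(spec)
        truth.to_frame().to_csv(out / "planted_truth.csv")
        manifest["synthetic_seed"] = spec.seed
    elif config.raw_records is not None:
        metadata = (RegionMetadata.from_csv(config.region_metadata)
                    if config.region_metadata else None)
        table = aggregate_counts(pd.read_csv(config.raw_records), metadata)
    else:
        table = RegionCountTable.from_wide_csv(config.wide_table)

    table, report = filter_matched(table)
    (out / "exclusion_report.json").write_text(
        json.dumps(report.to_dict(), indent=2))
    table.to_wide_csv(out / "cohort_wide.csv")
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "fosnet_version": __version__,
        "seed": config.seed,
        "parameters": _jsonify({k: v for k, v in asdict(config).items()
                                if k != "out_dir"}),
        "outputs": [],
    }
    seeds = np.random.SeedSequence(config.seed).spawn(8)

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("ingest")
        table = _load_table(config, out, manifest)
        manifest["n_animals"] = table.n_animals
        manifest["n_regions"] = table.n_regions
        manifest["group_sizes"] = {":".join(g): n for g, n in table.group_sizes().items()}

        stage("regional_stats")
        screen = RegionalActivationModel(table).fit(
            alpha=config.alpha,
            gate_on_interaction=config.gate_contrasts_on_interaction,
            fdr=config.fdr)
        screen.anova_frame.to_csv(out / "screen_anova.csv")
        screen.contrast_frame.to_csv(out / "screen_contrasts.csv", index=False)
        (out / "screen_summary.json").write_text(
            json.dumps(screen.counts, indent=2))

        hub_sets = {}
        for gi, group in enumerate(table.groups_present()):
            tag = _group_tag(group)
            gdir = out / tag
            gdir.mkdir(exist_ok=True)
            gseed = int(seeds[gi].generate_state(1)[0] % (2 ** 31))

            stage(f"connectivity [{tag}]")
            model = FunctionalNetworkModel(table, group, alpha=config.network_p)
            res = model.fit(inflation_grid=config.inflation_grid,
                            n_random=config.sw_random_graphs, seed=gseed)
            res.corr.r.to_csv(gdir / "correlation_r.csv")
            res.corr.p.to_csv(gdir / "correlation_p.csv")

            stage(f"network_metrics [{tag}]")
            res.network.adjacency.to_csv(gdir / "adjacency.csv")
            pd.DataFrame(res.network.edge_list(), columns=["region_a", "region_b"]
                         ).to_csv(gdir / "edges.tsv", sep="\t", index=False)
            nx.write_graphml(res.network.to_networkx(active_only=False),
                             gdir / "network.graphml")
            res.centrality.frame.to_csv(gdir / "centrality.csv")
            if res.clusters is not None:
                res.clusters.labels.rename("cluster").to_csv(gdir / "clusters.csv")
            summary = res.graph_summary.to_dict()
            if res.clusters is not None:
                summary["mcl_inflation"] = res.clusters.inflation
                summary["mcl_modularity_q"] = res.clusters.modularity_q
                summary["mcl_n_clusters"] = res.clusters.n_clusters
            (gdir / "graph_summary.json").write_text(json.dumps(summary, indent=2))

            stage(f"null_models [{tag}]")
            if res.network.n_edges > 0:
                ens = res.simulate_null(
                    n_replicates=config.null_replicates, seed=gseed,
                    swaps_per_edge=config.swaps_per_edge,
                    n_random_sw=config.sw_random_graphs_null)
                ens.summary_frame().to_csv(gdir / "null_ensemble.csv", index=False)
            if config.run_sweep:
                sweep = threshold_sweep(
                    res.corr, p_grid=config.sweep_grid,
                    n_replicates=config.null_replicates, seed=gseed,
                    swaps_per_edge=config.swaps_per_edge,
                    n_random_sw=config.sw_random_graphs_null)
                sweep.to_csv(gdir / "threshold_sweep.csv", index=False)

            stage(f"hub_analysis [{tag}]")
            hub_sets[tag] = res.hubs
            pd.Series(sorted(res.hubs.hubs), name="hub").to_csv(
                gdir / "hubs.csv", index=False)
            ranking = hub_robustness(res.corr, base_p=config.network_p,
                                     prune_grid=config.prune_grid,
                                     top_fraction=config.top_fraction)
            ranking.frame.to_csv(gdir / "hub_robustness.csv")

        stage("hub_overlap")
        compare_hub_sets(hub_sets).to_csv(out / "hub_overlap.csv", index=False)
    except Exception as exc:  # annotate stage failures, keep partial outputs
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"].append({
                "path": str(path.relative_to(out)),
                "sha256": _sha256(path),
            })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
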