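"""End-to-end orchestration: counts -> Z-scores -> correlations -> network.

`infer` runs the whole inference chain (normalisation, recursive clustering,
pairwise DE Z-scores, combined correlations with the adaptive threshold, GO
sub-setting, pruning, statistics, centralities) and optionally writes the
artifacts plus a provenance record. `compare` produces the between-condition
reports (per-metric centrality deltas, consensus shifts, correlation
inversions). All stages are seeded; re-running with the same configuration
and inputs reproduces the outputs bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import correlation_engine, network_analytics, network_builder, noise_de
from .data_model import ExpressionMatrix, RegulatorAnnotation, normalize
from .recursive_clustering import recursive_cluster

log = logging.getLogger("scgrn")


@dataclass
class RunConfig:
    """All tunable parameters of the inference pipeline."""

    seed: int = 0
    # expressed-gene filter
    min_cells_expressed: int = 5
    # noise model / DE
    de_reshuffles: int = 3
    de_bins: int = 15
    de_min_group: int = 5
    # clustering
    clustering_min_size: int | None = None
    clustering_max_depth: int = 6
    clustering_n_hvg: int = 500
    clustering_hetero_cut_index: int = 5
    # correlation
    corr_fraction: float = 0.001
    corr_spearman_margin: float = 0.15
    # centralities
    pagerank_damping: float = 0.85

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class InferenceResult:
    tree: object
    zmat: noise_de.ZScoreMatrix
    table: correlation_engine.CorrelationTable
    network: network_builder.RegulatoryNetwork
    stats: network_builder.NetworkStats
    centralities: object
    config: RunConfig
    stage_log: list = field(default_factory=list)


def infer_correlation_table(expr: ExpressionMatrix, seed: int = 0,
                            min_size: int | None = None, max_depth: int = 6,
                            n_hvg: int = 500, hetero_cut_index: int = 5,
                            reshuffles: int = 3, fraction: float = 0.001,
                            spearman_margin: float = 0.15,
                            min_cells_expressed: int = 5,
                            de_bins: int = 15, de_min_group: int = 5):
    """Counts -> (ClusterTree, ZScoreMatrix, thresholded CorrelationTable)."""
    if not expr.normalized:
        expr = normalize(expr)
    tree = recursive_cluster(expr, min_size=min_size, max_depth=max_depth,
                             n_hvg=n_hvg, hetero_cut_index=hetero_cut_index)
    model = noise_de.fit_noise_model(expr, n_bins=de_bins,
                                     min_group=de_min_group, seed=seed,
                                     min_cells_expressed=min_cells_expressed)
    zmat = noise_de.zscore_matrix(expr, tree.leaf_cells(), model=model,
                                  reshuffles=reshuffles, seed=seed,
                                  min_cells_expressed=min_cells_expressed)
    table = correlation_engine.correlate(zmat, fraction=fraction,
                                         spearman_margin=spearman_margin)
    return tree, zmat, table


def infer(expr: ExpressionMatrix, regulators: RegulatorAnnotation,
          config: RunConfig | None = None,
          output_dir=None) -> InferenceResult:
    """Full inference: counts + regulator annotation -> network + statistics."""
    config = config or RunConfig()
    stage_log = []

    def record(stage, **info):
        stage_log.append({"stage": stage, **info})
        log.info("%s: %s", stage, info)

    record("input", n_genes=expr.n_genes, n_cells=expr.n_cells,
           sparsity=round(expr.sparsity(), 4))
    tree, zmat, table = infer_correlation_table(
        expr, seed=config.seed, min_size=config.clustering_min_size,
        max_depth=config.clustering_max_depth,
        n_hvg=config.clustering_n_hvg,
        hetero_cut_index=config.clustering_hetero_cut_index,
        reshuffles=config.de_reshuffles, fraction=config.corr_fraction,
        spearman_margin=config.corr_spearman_margin,
        min_cells_expressed=config.min_cells_expressed,
        de_bins=config.de_bins, de_min_group=config.de_min_group)
    record("clustering", n_leaves=tree.n_leaves)
    record("zscores", n_genes=len(zmat.genes), n_comparisons=zmat.n_comparisons)
    record("correlation", n_pairs=table.n_pairs,
           rho_thresh=round(table.rho_thresh, 4),
           kept=int(table.kept.sum()))

    network = network_builder.build_network(table, regulators)
    stats = network_builder.network_stats(network)
    record("network", n_nodes=stats.n_nodes, n_edges=stats.n_edges)
    cent = network_analytics.centralities(network,
                                          damping=config.pagerank_damping)
    record("centralities", n_nodes=len(cent))

    result = InferenceResult(tree=tree, zmat=zmat, table=table,
                             network=network, stats=stats, centralities=cent,
                             config=config, stage_log=stage_log)
    if output_dir is not None:
        _write_artifacts(result, expr, output_dir)
    return result


def _write_artifacts(result: InferenceResult, expr: ExpressionMatrix,
                     output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.tree.assignments_to_tsv(out / "clusters.tsv", expr.cells)
    result.tree.to_json(out / "cluster_tree.json")
    result.zmat.to_tsv(out / "zscores.tsv")
    result.table.to_tsv(out / "correlations.tsv", kept_only=True)
    result.network.to_edge_tsv(out / "network_edges.tsv")
    result.network.to_graphml(out / "network.graphml")
    result.centralities.to_csv(out / "centralities.tsv", sep="\t")
    with open(out / "stats.json", "w") as fh:
        json.dump(result.stats.to_dict(), fh, indent=1)
    with open(out / "provenance.json", "w") as fh:
        json.dump({"config": result.config.to_dict(),
                   "stages": result.stage_log}, fh, indent=1)


def compare(result_a: InferenceResult, result_b: InferenceResult,
            top_n: int = 1000, strong: float = 1.0,
            de_pvalues=None) -> dict:
    """Between-condition reports: deltas, consensus shifts, inversions."""
    deltas = {
        m: network_analytics.delta_centrality(
            result_a.centralities, result_b.centralities, metric=m,
            top_n=top_n, de_pvalues=de_pvalues)
        for m in network_analytics.METRICS
    }
    consensus = network_analytics.consensus_shift(result_a.centralities,
                                                  result_b.centralities)
    inversions = network_analytics.find_inversions(result_a.table,
                                                   result_b.table,
                                                   strong=strong)
    return {"deltas": deltas, "consensus": consensus,
            "inversions": inversions}
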