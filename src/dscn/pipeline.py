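"""End-to-end orchestration: inputs -> networks -> clusters -> ranked pairs."""

from __future__ import annotations

import json
import logging
import os
import platform
from dataclasses import dataclass

from . import __version__
from .cluster import ClusterAssignment, cluster_laplacian, map_to_cellline
from .config import RunConfig
from .errors import InputError
from .io import (
    EssentialityTable,
    ExpressionMatrix,
    PPIEdgeList,
    TargetList,
    write_pair_ranking,
)
from .network import (
    WeightedNetwork,
    build_network,
    cellline_node_weights,
    correlation_affinity,
    laplacian,
    normalize_laplacian,
    tissue_node_weights,
)
from .pairs import PairContext, rank_all_pairs
from .scoring import WalkConfig
from .similarity import subnetwork_distance_table

log = logging.getLogger(__name__)


def shared_genes(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    cellline: ExpressionMatrix,
    ess: EssentialityTable,
    ppi: PPIEdgeList,
) -> list[str]:
    """Intersection of all data sources and the PPI node set, sorted."""
    genes = (
        set(tumor.genes)
        & set(normal.genes)
        & set(cellline.genes)
        & set(ess.genes)
        & ppi.nodes
    )
    if not genes:
        raise InputError("no genes shared by all data sources and the PPI network")
    return sorted(genes)


def build_tissue_network(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    ppi: PPIEdgeList,
    genes,
) -> WeightedNetwork:
    S = correlation_affinity(tumor, ppi, genes)
    w = tissue_node_weights(tumor, normal, genes)
    return build_network(S, w, kind="tissue", genes=genes)


def build_cellline_network(
    cellline: ExpressionMatrix,
    ess: EssentialityTable,
    ppi: PPIEdgeList,
    genes,
    lines=None,
) -> WeightedNetwork:
    S = correlation_affinity(cellline, ppi, genes)
    w = cellline_node_weights(ess, lines or ess.cell_lines, genes)
    return build_network(S, w, kind="cellline", genes=genes)


def cluster_tissue(net_t: WeightedNetwork, cfg: RunConfig) -> ClusterAssignment:
    lapN = normalize_laplacian(laplacian(net_t), net_t.node_weights)
    return cluster_laplacian(
        lapN,
        K_max=cfg.k_max,
        threshold=cfg.hartigan_threshold,
        seed=cfg.seed,
        restarts=cfg.kmeans_restarts,
        rule=cfg.hartigan_rule,
        nonnegative_only=cfg.nonnegative_eigs_only,
    )


@dataclass
class PipelineResult:
    genes: list[str]
    net_t: WeightedNetwork
    net_c: WeightedNetwork
    assign: ClusterAssignment
    pairs: list
    similarity: list[dict]


def run_pipeline(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    cellline: ExpressionMatrix,
    ess: EssentialityTable,
    ppi: PPIEdgeList,
    targets: TargetList,
    cfg: RunConfig | None = None,
) -> PipelineResult:
    """Steps 1-6 end to end on in-memory inputs."""
    cfg = cfg or RunConfig()
    genes = shared_genes(tumor, normal, cellline, ess, ppi)
    net_t = build_tissue_network(tumor, normal, ppi, genes)
    net_c = build_cellline_network(cellline, ess, ppi, genes)
    assign = cluster_tissue(net_t, cfg)
    map_to_cellline(assign, net_c)  # validates the shared universe
    ctx = PairContext(
        expr_c=cellline,
        ess=ess,
        skeleton=ppi,
        net_c=net_c,
        assign=assign,
        scheme=cfg.scheme,
        scope=cfg.scope,
        walk=WalkConfig(steps=cfg.walk_steps, seed=cfg.seed),
        diffusion_ratio=cfg.diffusion_ratio,
        min_samples=cfg.min_samples,
    )
    pairs = rank_all_pairs(targets, ctx)
    sim = subnetwork_distance_table(net_t, net_c, assign)
    return PipelineResult(
        genes=genes, net_t=net_t, net_c=net_c, assign=assign,
        pairs=pairs, similarity=sim,
    )


def write_outputs(result: PipelineResult, cfg: RunConfig, outdir) -> None:
    """Ranking, cluster table, similarity table and a reproducibility manifest."""
    os.makedirs(outdir, exist_ok=True)
    write_pair_ranking(result.pairs, os.path.join(outdir, "pairs.tsv"))
    with open(os.path.join(outdir, "clusters.tsv"), "w") as fh:
        fh.write("gene\tcluster\n")
        for g in result.assign.genes:
            fh.write(f"{g}\t{result.assign.labels[g]}\n")
    with open(os.path.join(outdir, "subnet_distance.tsv"), "w") as fh:
        fh.write("cluster\tn_genes\tscale\tdistance\n")
        for row in result.similarity:
            fh.write(
                f"{row['cluster']}\t{row['n_genes']}\t{row['scale']:.6g}\t"
                f"{row['distance']:.6g}\n"
            )
    manifest = {
        "dscn_version": __version__,
        "python": platform.python_version(),
        "config": cfg.to_dict(),
        "n_genes": len(result.genes),
        "K_prime": result.assign.K_prime,
        "n_pairs": len(result.pairs),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
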