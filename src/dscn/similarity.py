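"""Tissue / cell-line subnetwork comparability and distance.

For each matched cluster the cell-line node weights are rescaled so both
diagonals share the same trace, both Laplacians get their edge weights
renormalized by node importance (keeping original signs), and the distance
is the sum of squared off-diagonal differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cluster import ClusterAssignment
from .errors import InputError
from .network import (
    LaplacianMatrix,
    WeightedNetwork,
    induced_subnetwork,
    laplacian,
)

log = logging.getLogger(__name__)


@dataclass
class NormalizedSubnetPair:
    tissue_lap: LaplacianMatrix
    cellline_lap: LaplacianMatrix
    scale: float

    def __post_init__(self):
        t = np.trace(self.tissue_lap.L)
        c = np.trace(self.cellline_lap.L)
        if abs(t - c) > 1e-9 * max(1.0, abs(t)):
            raise InputError(f"diagonal traces differ after matching: {t} vs {c}")


def match_node_weights(d_tissue: np.ndarray, d_cellline: np.ndarray):
    """Scale the cell-line weights by sum(tissue)/sum(cellline) so the two
    diagonals have equal sums. Returns (scaled vector, scale)."""
    d_tissue = np.asarray(d_tissue, dtype=float)
    d_cellline = np.asarray(d_cellline, dtype=float)
    if d_tissue.shape != d_cellline.shape:
        raise InputError("node-weight vectors have different lengths")
    c_sum = d_cellline.sum()
    if c_sum == 0.0:
        raise InputError("cell-line node weights sum to zero; cannot rescale")
    scale = float(d_tissue.sum() / c_sum)
    return d_cellline * scale, scale


def renormalize_edges(lap: LaplacianMatrix) -> LaplacianMatrix:
    """Rescale off-diagonals: entry (j, l) becomes w_jl * |w_j| / sum_x |w_jx|
    with w_jl the original signed edge weight and w_j the diagonal.

    Rows without edges keep zero off-diagonals (logged).
    """
    L = lap.L
    n = len(lap.genes)
    S = -L.copy()
    np.fill_diagonal(S, 0.0)
    diag = np.diag(L)
    out = np.zeros_like(L)
    empty = 0
    for j in range(n):
        denom = np.abs(S[j]).sum()
        if denom == 0.0:
            empty += 1
        else:
            out[j] = S[j] * abs(diag[j]) / denom
        out[j, j] = diag[j]
    if empty:
        log.debug("%d zero-edge rows kept zero off-diagonals", empty)
    return LaplacianMatrix(genes=list(lap.genes), L=out, normalized=True)


def subnetwork_distance(pair: NormalizedSubnetPair) -> float:
    """Sum of squared off-diagonal differences between the two matrices."""
    A, B = pair.tissue_lap.L, pair.cellline_lap.L
    if A.shape != B.shape:
        raise InputError(f"shape mismatch: {A.shape} vs {B.shape}")
    diff = A - B
    np.fill_diagonal(diff, 0.0)
    return float((diff * diff).sum())


def normalized_subnet_pair(
    net_t_sub: WeightedNetwork, net_c_sub: WeightedNetwork
) -> NormalizedSubnetPair:
    """Build the comparable Laplacian pair for one matched cluster."""
    if net_t_sub.genes != net_c_sub.genes:
        raise InputError("subnetworks must share the same gene order")
    scaled, scale = match_node_weights(net_t_sub.node_weights, net_c_sub.node_weights)
    lap_t = laplacian(net_t_sub)
    lap_c = LaplacianMatrix(
        genes=list(net_c_sub.genes),
        L=np.diag(scaled) - net_c_sub.affinity,
        normalized=False,
    )
    return NormalizedSubnetPair(
        tissue_lap=renormalize_edges(lap_t),
        cellline_lap=renormalize_edges(lap_c),
        scale=scale,
    )


def subnetwork_distance_table(
    net_t: WeightedNetwork, net_c: WeightedNetwork, assign: ClusterAssignment
) -> list[dict]:
    """Per-cluster distance diagnostics between tissue and cell-line."""
    rows = []
    for cid in range(1, assign.K_prime + 1):
        genes = assign.cluster_genes(cid)
        sub_t = induced_subnetwork(net_t, genes)
        sub_c = induced_subnetwork(net_c, genes)
        try:
            pair = normalized_subnet_pair(sub_t, sub_c)
            dist = subnetwork_distance(pair)
            scale = pair.scale
        except InputError as exc:
            log.warning("cluster %d skipped in similarity table: %s", cid, exc)
            dist, scale = float("nan"), float("nan")
        rows.append(
            {"cluster": cid, "n_genes": len(genes), "scale": scale, "distance": dist}
        )
    return rows
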