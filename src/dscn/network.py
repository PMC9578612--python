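"""Weighted-network construction on a shared PPI skeleton.

A network is an affinity matrix S (edge weights = Pearson correlations,
restricted to PPI edges) plus a node-weight vector (diagonal D): tissue
networks carry tumor-vs-normal log2 fold changes, cell-line networks carry
mean log2 essentiality. The Laplacian is L = D - S, and its normalized form
rescales each row's off-diagonals so their absolute sum equals the absolute
diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InputError, InternalError
from .io import EssentialityTable, ExpressionMatrix, PPIEdgeList

log = logging.getLogger(__name__)

_SYM_TOL = 1e-9


@dataclass
class WeightedNetwork:
    """PPI skeleton with correlation edge weights and per-gene node weights."""

    genes: list[str]
    affinity: np.ndarray
    node_weights: np.ndarray
    kind: str  # "tissue" | "cellline"

    def __post_init__(self):
        self.affinity = np.asarray(self.affinity, dtype=float)
        self.node_weights = np.asarray(self.node_weights, dtype=float)
        n = len(self.genes)
        if self.affinity.shape != (n, n):
            raise InputError(
                f"affinity shape {self.affinity.shape} does not match {n} genes"
            )
        if self.node_weights.shape != (n,):
            raise InputError("node-weight length does not match gene count")
        if np.abs(np.diag(self.affinity)).max(initial=0.0) > _SYM_TOL:
            raise InternalError("affinity matrix has nonzero diagonal")
        if n and np.abs(self.affinity - self.affinity.T).max() > _SYM_TOL:
            raise InternalError("affinity matrix is asymmetric beyond tolerance")
        if n and np.abs(self.affinity).max() > 1.0 + 1e-9:
            raise InternalError("affinity entries exceed 1 in absolute value")
        if not np.all(np.isfinite(self.node_weights)):
            raise InputError("non-finite node weights")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n(self) -> int:
        return len(self.genes)

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise InputError(f"gene {gene!r} not in network") from None

    def neighbors(self, i: int) -> np.ndarray:
        """Indices with a (nonzero-weight) edge to node i."""
        return np.flatnonzero(self.affinity[i] != 0.0)


def induced_subnetwork(net: WeightedNetwork, genes) -> WeightedNetwork:
    """Subnetwork on ``genes`` keeping only internal edges (order preserved)."""
    keep = [g for g in net.genes if g in set(genes)]
    idx = np.array([net.index(g) for g in keep], dtype=int)
    return WeightedNetwork(
        genes=keep,
        affinity=net.affinity[np.ix_(idx, idx)],
        node_weights=net.node_weights[idx],
        kind=net.kind,
    )


def _pairwise_pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    x, y = x[ok], y[ok]
    xd, yd = x - x.mean(), y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0.0:
        return np.nan
    return float((xd * yd).sum() / denom)


def correlation_affinity(
    expr: ExpressionMatrix, skeleton: PPIEdgeList, genes
) -> np.ndarray:
    """Pearson-correlation edge weights on the PPI skeleton.

    S[a, b] is the sample Pearson r for each PPI edge (a, b) among ``genes``
    and 0 elsewhere. Correlations use pairwise-complete samples; edges
    touching a zero-variance gene get weight 0 (logged).
    """
    genes = list(genes)
    if expr.n_samples < 3:
        raise InputError(
            f"need >=3 samples to compute correlations, got {expr.n_samples}"
        )
    missing = [g for g in genes if g not in set(expr.genes)]
    if missing:
        raise InputError(f"genes absent from expression matrix: {missing[:10]}")
    pos = {g: i for i, g in enumerate(genes)}
    rows = np.array([expr.genes.index(g) for g in genes])
    X = expr.values[rows]
    n = len(genes)
    S = np.zeros((n, n), dtype=float)

    fast = np.all(np.isfinite(X))
    if fast:
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X)
        C = np.atleast_2d(C)
    zero_var_edges = 0
    for a, b, _score in skeleton.edges:
        ia, ib = pos.get(a), pos.get(b)
        if ia is None or ib is None:
            continue
        r = C[ia, ib] if fast else _pairwise_pearson(X[ia], X[ib])
        if not np.isfinite(r):
            zero_var_edges += 1
            r = 0.0
        r = float(np.clip(r, -1.0, 1.0))
        S[ia, ib] = r
        S[ib, ia] = r
    if zero_var_edges:
        log.warning("%d PPI edges had undefined correlation; weight set to 0",
                    zero_var_edges)
    np.fill_diagonal(S, 0.0)
    return S


def tissue_node_weights(
    tumor: ExpressionMatrix, normal: ExpressionMatrix, genes
) -> np.ndarray:
    """Per-gene log2 fold change: mean tumor expression minus mean normal.

    Inputs are assumed log2-scale, so the difference of means is the log2
    fold change; positive values mean higher expression in tumor.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in set(tumor.genes) or g not in set(normal.genes)]
    if missing:
        raise InputError(f"genes missing from tumor or normal matrix: {missing[:10]}")
    t_idx = [tumor.genes.index(g) for g in genes]
    n_idx = [normal.genes.index(g) for g in genes]
    t_mean = np.nanmean(tumor.values[t_idx], axis=1)
    n_mean = np.nanmean(normal.values[n_idx], axis=1)
    return t_mean - n_mean


def cellline_node_weights(ess: EssentialityTable, lines, genes) -> np.ndarray:
    """Mean log2 essentiality of each gene over the retained cell lines."""
    lines = list(lines)
    if not lines:
        raise DegenerateInputError("empty cell-line set for node weights")
    unknown = [l for l in lines if l not in set(ess.cell_lines)]
    if unknown:
        raise InputError(f"unknown cell lines: {unknown[:10]}")
    missing = [g for g in genes if g not in set(ess.genes)]
    if missing:
        raise InputError(f"genes absent from essentiality table: {missing[:10]}")
    g_idx = [ess.genes.index(g) for g in genes]
    l_idx = [ess.cell_lines.index(l) for l in lines]
    return np.nanmean(ess.values[np.ix_(g_idx, l_idx)], axis=1)


def build_network(affinity, node_weights, kind: str, genes=None) -> WeightedNetwork:
    """Assemble and validate a weighted network (affinity + diagonal weights)."""
    affinity = np.asarray(affinity, dtype=float)
    node_weights = np.asarray(node_weights, dtype=float)
    if genes is None:
        genes = [f"G{i}" for i in range(len(node_weights))]
    return WeightedNetwork(
        genes=list(genes), affinity=affinity, node_weights=node_weights, kind=kind
    )


@dataclass
class LaplacianMatrix:
    genes: list[str]
    L: np.ndarray
    normalized: bool

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        n = len(self.genes)
        if self.L.shape != (n, n):
            raise InputError("Laplacian shape does not match gene count")


def laplacian(net: WeightedNetwork) -> LaplacianMatrix:
    """L = D - S with D = diag(node weights)."""
    L = np.diag(net.node_weights) - net.affinity
    return LaplacianMatrix(genes=list(net.genes), L=L, normalized=False)


def normalize_laplacian(lap: LaplacianMatrix, node_weights) -> LaplacianMatrix:
    """Row-rescale off-diagonals so each connected row's absolute off-diagonal
    sum equals the absolute value of its diagonal node weight.

    Off-diagonal (i, j) becomes -|w_ij * w_i| / sum_k |w_ik| where w_ik are
    the row's edge weights; rows without edges keep zero off-diagonals. The
    result is generally asymmetric and is deliberately not symmetrized.
    """
    if lap.normalized:
        raise InputError("Laplacian is already normalized")
    node_weights = np.asarray(node_weights, dtype=float)
    n = len(lap.genes)
    S = -lap.L.copy()
    np.fill_diagonal(S, 0.0)
    out = np.zeros((n, n), dtype=float)
    abs_rows = np.abs(S).sum(axis=1)
    empty = 0
    for i in range(n):
        if abs_rows[i] == 0.0:
            empty += 1
        else:
            out[i] = -np.abs(S[i] * node_weights[i]) / abs_rows[i]
        out[i, i] = node_weights[i]
    if empty:
        log.debug("%d rows without edges kept zero off-diagonals", empty)
    return LaplacianMatrix(genes=list(lap.genes), L=out, normalized=True)
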