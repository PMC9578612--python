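"""Spectral clustering of the normalized tissue Laplacian.

The row-normalized Laplacian is asymmetric, so by default the
eigendecomposition is taken on its symmetric part (L' + L'^T) / 2, which has
a real spectrum. K-means runs on the rows of the k smallest eigenvectors,
and the number of clusters is chosen with Hartigan's statistic

    H(K) = (W_K / W_{K+1} - 1) * (n - K - 1)

with W_K the total within-cluster sum of squares of K-means with K clusters
on the width-K embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.cluster import KMeans

from .errors import ConfigError, DegenerateInputError, InputError
from .network import LaplacianMatrix, WeightedNetwork, induced_subnetwork

log = logging.getLogger(__name__)

K_HARD_CAP = 10  # clusters are constrained to at most 10


@dataclass
class SpectralEmbedding:
    genes: list[str]
    eigenvalues: np.ndarray  # selected, ascending
    H: np.ndarray            # n x k eigenvector matrix


def eigendecompose(
    lapN: LaplacianMatrix, k: int, nonnegative_only: bool = False
) -> SpectralEmbedding:
    """Eigenpairs of the symmetrized normalized Laplacian, smallest first.

    With ``nonnegative_only`` the selection is restricted to eigenvalues
    >= -1e-9 (and it is an error if fewer than ``k`` remain). By default the
    k algebraically smallest eigenvalues are used: the symmetrized operator
    is only approximately positive semi-definite, and its slightly negative
    eigenvalues carry exactly the smooth, cluster-indicating eigenvectors
    that the embedding needs.
    """
    if not lapN.normalized:
        raise InputError("eigendecompose expects a normalized Laplacian")
    n = len(lapN.genes)
    if not 1 <= k <= n:
        raise InputError(f"embedding width k={k} out of range 1..{n}")
    M = 0.5 * (lapN.L + lapN.L.T)
    vals, vecs = np.linalg.eigh(M)
    if nonnegative_only:
        keep = vals >= -1e-9
        if keep.sum() < k:
            raise InputError(
                f"only {int(keep.sum())} non-negative eigenvalues available, "
                f"need k={k}"
            )
        vals, vecs = vals[keep], vecs[:, keep]
    return SpectralEmbedding(
        genes=list(lapN.genes), eigenvalues=vals[:k].copy(), H=vecs[:, :k].copy()
    )


@dataclass
class ClusterAssignment:
    """Gene -> cluster label (1..K') plus the per-K Hartigan diagnostics."""

    genes: list[str]
    labels: dict[str, int]
    K_prime: int
    quality: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 1 <= self.K_prime <= K_HARD_CAP:
            raise InputError(f"K'={self.K_prime} outside 1..{K_HARD_CAP}")
        missing = [g for g in self.genes if g not in self.labels]
        if missing:
            raise InputError(f"unlabeled genes: {missing[:10]}")
        present = set(self.labels[g] for g in self.genes)
        if present != set(range(1, self.K_prime + 1)):
            raise InputError(
                f"cluster ids {sorted(present)} are not exactly 1..{self.K_prime}"
            )

    def cluster_genes(self, cid: int) -> list[str]:
        return [g for g in self.genes if self.labels[g] == cid]


def _kmeans_w(X: np.ndarray, K: int, seed: int, restarts: int):
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed)
    labels = km.fit_predict(X)
    return float(km.inertia_), labels


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..K in order of first appearance (determinism)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    nxt = 1
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def hartigan_select_k(
    H_builder: Callable[[int], np.ndarray],
    genes,
    K_max: int = 10,
    threshold: float = 10.0,
    seed: int = 0,
    restarts: int = 10,
    rule: str = "argmin",
) -> ClusterAssignment:
    """Choose the cluster count with Hartigan's statistic and return labels.

    ``H_builder(k)`` must return the n x k embedding used for K = k.
    Two acceptance rules are provided:

    - ``"argmin"`` (default): pick the K in 1..K_lim-1 minimizing H(K).
      Because each candidate K is evaluated on its own width-K embedding,
      the true cluster count shows up as a sharply negative H (W_K collapses
      at the right K while the next embedding re-introduces variance).
    - ``"threshold"``: the classical rule, smallest K with H(K) <= threshold
      (falling back to K_lim when none qualifies).
    """
    genes = list(genes)
    n = len(genes)
    if n < 2:
        raise DegenerateInputError("need at least 2 genes to cluster")
    if rule not in ("argmin", "threshold"):
        raise ConfigError(f"unknown Hartigan rule {rule!r}")
    K_lim = min(K_max, K_HARD_CAP, n - 1)
    K_lim = max(K_lim, 1)

    W: dict[int, float] = {}
    L: dict[int, np.ndarray] = {}
    for K in range(1, K_lim + 1):
        X = np.asarray(H_builder(K), dtype=float)
        if X.shape[0] != n:
            raise InputError("embedding row count does not match gene count")
        W[K], L[K] = _kmeans_w(X, K, seed, restarts)

    quality: dict[int, float] = {}
    for K in range(1, K_lim):
        denom_df = n - K - 1
        if W[K + 1] == 0.0:
            ratio = 1.0 if W[K] == 0.0 else np.inf
        else:
            ratio = W[K] / W[K + 1]
        quality[K] = (ratio - 1.0) * denom_df if np.isfinite(ratio) else np.inf

    if W[1] == 0.0:
        K_prime = 1  # degenerate: a single perfect cluster
    elif not quality:
        K_prime = 1
    elif rule == "argmin":
        K_prime = min(quality, key=lambda K: (quality[K], K))
    else:
        accepted = [K for K in sorted(quality) if quality[K] <= threshold]
        K_prime = accepted[0] if accepted else K_lim

    labels = _canonical_labels(L[K_prime])
    return ClusterAssignment(
        genes=genes,
        labels={g: int(l) for g, l in zip(genes, labels)},
        K_prime=int(K_prime),
        quality=quality,
    )


def cluster_laplacian(
    lapN: LaplacianMatrix,
    K_max: int = 10,
    threshold: float = 10.0,
    seed: int = 0,
    restarts: int = 10,
    rule: str = "argmin",
    nonnegative_only: bool = False,
) -> ClusterAssignment:
    """End-to-end Step-3 clustering of a normalized tissue Laplacian."""

    def builder(k: int) -> np.ndarray:
        return eigendecompose(lapN, k, nonnegative_only=nonnegative_only).H

    return hartigan_select_k(
        builder, lapN.genes, K_max=K_max, threshold=threshold,
        seed=seed, restarts=restarts, rule=rule,
    )


def map_to_cellline(
    assign: ClusterAssignment, net_c: WeightedNetwork
) -> list[WeightedNetwork]:
    """Induce each tissue cluster on the cell-line network by shared names.

    Returns one induced subnetwork per cluster id 1..K'; cross-cluster
    edges are dropped by construction.
    """
    if set(assign.genes) != set(net_c.genes):
        raise InputError("cluster assignment and cell-line network cover "
                         "different gene universes")
    return [
        induced_subnetwork(net_c, assign.cluster_genes(cid))
        for cid in range(1, assign.K_prime + 1)
    ]
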