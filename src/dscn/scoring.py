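"""Target impact scores: most-probable path, random walk, diffusion tiers.

Every scheme decomposes as IS(T) = w_T + propagation, where w_T is the
target's own node weight and the propagation term accumulates node-weight
x edge-weight products over the part of the network the target can reach.
More negative = more impactful.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np

from .cluster import ClusterAssignment
from .errors import ConfigError, InputError
from .network import WeightedNetwork, induced_subnetwork

log = logging.getLogger(__name__)

SCHEMES = ("most_probable", "random_walk", "diffusion")
SCOPES = ("local", "global")


@dataclass
class ImpactScore:
    target: str
    scheme: str
    scope: str
    value: float
    base: float          # w_T, the target's own weight
    propagation: float   # network term; value == base + propagation

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise InputError(f"non-finite impact score for {self.target}")


@dataclass
class WalkConfig:
    """Random-walk settings; ``steps=None`` means 2n (n = network size)."""

    steps: int | None = None
    seed: int = 0

    def resolved_steps(self, n: int) -> int:
        steps = 2 * n if self.steps is None else self.steps
        if steps < 1:
            raise ConfigError(f"walk steps must be >= 1, got {steps}")
        return steps


def most_probable_path_score(net: WeightedNetwork, target: str) -> ImpactScore:
    """IS = w_T + min over neighbors N of (w_N * w_{T,N}).

    With no neighbors the propagation term is 0.
    """
    t = net.index(target)
    w_t = float(net.node_weights[t])
    nbrs = net.neighbors(t)
    if nbrs.size == 0:
        prop = 0.0
    else:
        products = net.node_weights[nbrs] * net.affinity[t, nbrs]
        prop = float(products.min())
    return ImpactScore(target, "most_probable", "global", w_t + prop, w_t, prop)


def transition_matrix(net: WeightedNetwork) -> np.ndarray:
    """Row-stochastic kernel P[j, i] = |w_ji| / sum_x |w_jx|.

    Absolute edge weights are used so the kernel is a proper probability
    matrix; edge signs still enter the scores through the weight products.
    Isolated nodes are absorbing (self-probability 1).
    """
    A = np.abs(net.affinity)
    rowsum = A.sum(axis=1)
    P = np.zeros_like(A)
    connected = rowsum > 0
    P[connected] = A[connected] / rowsum[connected, None]
    for j in np.flatnonzero(~connected):
        P[j, j] = 1.0
    return P


def simulate_walk(P: np.ndarray, start: int, steps: int, rng: np.random.Generator):
    """Run one walk, returning {node: first-visit parent} for nodes != start."""
    n = P.shape[0]
    parents: dict[int, int] = {}
    visited = {start}
    current = start
    for _ in range(steps):
        nxt = int(rng.choice(n, p=P[current]))
        if nxt not in visited:
            visited.add(nxt)
            parents[nxt] = current
        current = nxt
    return parents


def random_walk_score(
    net: WeightedNetwork, target: str, cfg: WalkConfig | None = None
) -> ImpactScore:
    """Single seeded walk of 2n steps; each first-visited node contributes
    w_i * w_{i,Pa(i)} with Pa(i) the node that first reached it."""
    cfg = cfg or WalkConfig()
    t = net.index(target)
    w_t = float(net.node_weights[t])
    if net.neighbors(t).size == 0:
        log.info("random walk from isolated target %s: IS = w_T", target)
        return ImpactScore(target, "random_walk", "global", w_t, w_t, 0.0)
    P = transition_matrix(net)
    rng = np.random.default_rng(cfg.seed)
    parents = simulate_walk(P, t, cfg.resolved_steps(net.n), rng)
    prop = 0.0
    for i, pa in parents.items():
        prop += float(net.node_weights[i] * net.affinity[i, pa])
    return ImpactScore(target, "random_walk", "global", w_t + prop, w_t, prop)


def diffusion_tiers(net: WeightedNetwork, target: str) -> dict[str, int]:
    """BFS tiers from the target: tier 0 = target, tier t = distance t.

    Unreachable nodes are omitted.
    """
    t = net.index(target)
    tier = {t: 0}
    queue = deque([t])
    while queue:
        j = queue.popleft()
        for i in net.neighbors(j):
            i = int(i)
            if i not in tier:
                tier[i] = tier[j] + 1
                queue.append(i)
    return {net.genes[i]: d for i, d in tier.items()}


def diffusion_score(
    net: WeightedNetwork, target: str, ratio: bool = False
) -> ImpactScore:
    """Deterministic tiered propagation.

    Each reachable node i contributes w_i * (sum of its edges to the tier
    above + sum of its edges within its own tier); with ``ratio`` the
    contribution is (edge sum) / w_i instead of the product.
    """
    tiers = diffusion_tiers(net, target)
    idx_tier = {net.index(g): d for g, d in tiers.items()}
    t = net.index(target)
    w_t = float(net.node_weights[t])
    prop = 0.0
    for i, d in idx_tier.items():
        if i == t:
            continue
        edge_sum = 0.0
        for j in net.neighbors(i):
            j = int(j)
            dj = idx_tier.get(j)
            if dj is None:
                continue
            if dj == d - 1 or (dj == d and j != i):
                edge_sum += float(net.affinity[i, j])
        w_i = float(net.node_weights[i])
        if ratio:
            if w_i == 0.0:
                raise InputError(
                    f"diffusion ratio undefined: zero node weight at {net.genes[i]}"
                )
            prop += edge_sum / w_i
        else:
            prop += w_i * edge_sum
    return ImpactScore(target, "diffusion", "global", w_t + prop, w_t, prop)


def impact_score(
    net: WeightedNetwork,
    target: str,
    scheme: str = "diffusion",
    scope: str = "local",
    assign: ClusterAssignment | None = None,
    walk: WalkConfig | None = None,
    diffusion_ratio: bool = False,
) -> ImpactScore:
    """Dispatch a scoring scheme on the global network or the target's
    cluster-induced local subnetwork."""
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scope not in SCOPES:
        raise ConfigError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    if scope == "local":
        if assign is None:
            raise ConfigError("local scope requires a cluster assignment")
        cid = assign.labels.get(target)
        if cid is None:
            raise InputError(f"target {target!r} missing from cluster assignment")
        scoped = induced_subnetwork(net, assign.cluster_genes(cid))
    else:
        scoped = net
    if scheme == "most_probable":
        score = most_probable_path_score(scoped, target)
    elif scheme == "random_walk":
        score = random_walk_score(scoped, target, walk)
    else:
        score = diffusion_score(scoped, target, ratio=diffusion_ratio)
    score.scope = scope
    return score
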