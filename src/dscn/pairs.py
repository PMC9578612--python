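"""First-target knockdown by subsampling and combination scoring.

Knocking down T1 is modelled by discarding cell-line expression samples
(and essentiality screens) in which T1 sits at or above its own mean; the
cell-line network is rebuilt on the retained samples and T2 is re-scored on
it, giving IS(T2|T1). The combined score IS(T1,T2) = IS(T1) + IS(T2|T1) is
evaluated for both orders and the smaller (more impactful) kept; a pair is
called synergistic when the combined score beats the sum of the marginals.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterAssignment
from .errors import ConfigError, DegenerateInputError, InputError
from .io import EssentialityTable, ExpressionMatrix, PPIEdgeList, TargetList
from .network import (
    WeightedNetwork,
    build_network,
    cellline_node_weights,
    correlation_affinity,
)
from .scoring import WalkConfig, impact_score

log = logging.getLogger(__name__)


@dataclass
class PairScore:
    """Scored ordered pair; t1 is the first (knocked-down) target of the
    winning order."""

    t1: str
    t2: str
    is_t1: float
    is_t2_given_t1: float
    is_pair: float
    is_t2_marginal: float
    synergy: bool
    order_policy: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.t1 == self.t2:
            raise InputError(f"pair with identical genes: {self.t1}")
        if abs(self.is_pair - (self.is_t1 + self.is_t2_given_t1)) > 1e-9:
            raise InputError("combined score is not the sum of its components")

    @property
    def key(self) -> frozenset:
        return frozenset((self.t1, self.t2))


@dataclass
class KnockdownSubsample:
    target: str
    kept_expression_samples: list[str]
    kept_essentiality_lines: list[str]
    thresholds: dict[str, float]


def subsample_knockdown(
    expr_c: ExpressionMatrix,
    ess: EssentialityTable,
    target: str,
    min_samples: int = 3,
    subsample_essentiality: bool = True,
) -> KnockdownSubsample:
    """Keep expression samples and essentiality lines with the target's value
    strictly below its mean in that source.

    Samples exactly at the mean are removed. ``subsample_essentiality=False``
    retains every essentiality line (single-sample variant).
    """
    e_row = expr_c.row(target)
    e_mean = float(np.nanmean(e_row))
    kept_samples = [s for s, v in zip(expr_c.samples, e_row) if v < e_mean]
    if len(kept_samples) < min_samples:
        raise DegenerateInputError(
            f"knockdown of {target}: only {len(kept_samples)} expression "
            f"samples below the mean (need >= {min_samples})"
        )
    thresholds = {"expression": e_mean}
    if subsample_essentiality:
        s_row = ess.row(target)
        s_mean = float(np.nanmean(s_row))
        kept_lines = [l for l, v in zip(ess.cell_lines, s_row) if v < s_mean]
        if len(kept_lines) < 1:
            raise DegenerateInputError(
                f"knockdown of {target}: no essentiality line below the mean"
            )
        thresholds["essentiality"] = s_mean
    else:
        kept_lines = list(ess.cell_lines)
    return KnockdownSubsample(
        target=target,
        kept_expression_samples=kept_samples,
        kept_essentiality_lines=kept_lines,
        thresholds=thresholds,
    )


def conditional_network(
    expr_c: ExpressionMatrix,
    ess: EssentialityTable,
    skeleton: PPIEdgeList,
    sub: KnockdownSubsample,
    genes,
) -> WeightedNetwork:
    """Rebuild the cell-line network on the knockdown subsample."""
    expr_sub = expr_c.subset_samples(sub.kept_expression_samples)
    S = correlation_affinity(expr_sub, skeleton, genes)
    w = cellline_node_weights(ess, sub.kept_essentiality_lines, genes)
    return build_network(S, w, kind="cellline", genes=genes)


def conditional_score(
    net_sub: WeightedNetwork,
    t2: str,
    scheme: str,
    scope: str,
    assign: ClusterAssignment | None,
    walk: WalkConfig | None = None,
    diffusion_ratio: bool = False,
) -> float:
    """IS(T2|T1): score T2 on the conditional network through the same
    tissue clustering."""
    return impact_score(
        net_sub, t2, scheme=scheme, scope=scope, assign=assign,
        walk=walk, diffusion_ratio=diffusion_ratio,
    ).value


@dataclass
class PairContext:
    """Everything needed to score pairs, with per-target caches."""

    expr_c: ExpressionMatrix
    ess: EssentialityTable
    skeleton: PPIEdgeList
    net_c: WeightedNetwork
    assign: ClusterAssignment | None
    scheme: str = "diffusion"
    scope: str = "local"
    walk: WalkConfig | None = None
    diffusion_ratio: bool = False
    min_samples: int = 3
    subsample_policy: str = "mean"  # "mean" | "none"
    subsample_essentiality: bool = True
    _marginal: dict = field(default_factory=dict, repr=False)
    _conditional_nets: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.subsample_policy not in ("mean", "none"):
            raise ConfigError(f"unknown subsample policy {self.subsample_policy!r}")

    def marginal_score(self, gene: str) -> float:
        if gene not in self._marginal:
            self._marginal[gene] = impact_score(
                self.net_c, gene, scheme=self.scheme, scope=self.scope,
                assign=self.assign, walk=self.walk,
                diffusion_ratio=self.diffusion_ratio,
            ).value
        return self._marginal[gene]

    def knockdown_net(self, gene: str) -> WeightedNetwork:
        if gene not in self._conditional_nets:
            if self.subsample_policy == "none":
                sub = KnockdownSubsample(
                    target=gene,
                    kept_expression_samples=list(self.expr_c.samples),
                    kept_essentiality_lines=list(self.ess.cell_lines),
                    thresholds={},
                )
            else:
                sub = subsample_knockdown(
                    self.expr_c, self.ess, gene,
                    min_samples=self.min_samples,
                    subsample_essentiality=self.subsample_essentiality,
                )
            self._conditional_nets[gene] = conditional_network(
                self.expr_c, self.ess, self.skeleton, sub, self.net_c.genes
            )
        return self._conditional_nets[gene]


def score_pair(t1: str, t2: str, ctx: PairContext) -> PairScore:
    """Score both knockdown orders and keep the more impactful one."""
    if t1 == t2:
        raise InputError(f"cannot pair gene {t1!r} with itself")
    totals = {}
    parts = {}
    for first, second in ((t1, t2), (t2, t1)):
        is_first = ctx.marginal_score(first)
        net_sub = ctx.knockdown_net(first)
        is_second_cond = conditional_score(
            net_sub, second, ctx.scheme, ctx.scope, ctx.assign,
            walk=ctx.walk, diffusion_ratio=ctx.diffusion_ratio,
        )
        totals[(first, second)] = is_first + is_second_cond
        parts[(first, second)] = (is_first, is_second_cond)
    ordered = sorted(totals, key=lambda o: (totals[o], o))
    win = ordered[0]
    is_t1, is_t2_given_t1 = parts[win]
    is_t2_marginal = ctx.marginal_score(win[1])
    is_pair = totals[win]
    synergy = is_pair < ctx.marginal_score(win[0]) + is_t2_marginal
    return PairScore(
        t1=win[0],
        t2=win[1],
        is_t1=is_t1,
        is_t2_given_t1=is_t2_given_t1,
        is_pair=is_pair,
        is_t2_marginal=is_t2_marginal,
        synergy=synergy,
        order_policy={
            "order_totals": {f"{a}->{b}": v for (a, b), v in totals.items()},
            "rule": "min",
        },
    )


def rank_all_pairs(targets: TargetList, ctx: PairContext) -> list[PairScore]:
    """Score every unordered pair over the druggable-target universe present
    in the network; ascending by combined score (lexicographic tiebreak)."""
    universe = sorted(targets.all_genes & set(ctx.net_c.genes))
    if len(universe) < 2:
        raise InputError(
            f"need >= 2 druggable targets in the network, found {len(universe)}"
        )
    scored = [score_pair(a, b, ctx) for a, b in itertools.combinations(universe, 2)]
    scored.sort(key=lambda p: (p.is_pair, p.t1, p.t2))
    return scored


def predicted_knockdown_foldchange(
    expr: ExpressionMatrix, target: str, neighbors
) -> dict[str, float]:
    """Predicted log2 fold change of each neighbor gene under target
    knockdown: low-target-group mean minus high-target-group mean, groups
    split at the target's mean (values exactly at the mean are dropped)."""
    neighbors = list(neighbors)
    missing = [g for g in neighbors if g not in set(expr.genes)]
    if missing:
        raise InputError(f"neighbor genes absent from expression: {missing[:10]}")
    t_row = expr.row(target)
    mean = float(np.nanmean(t_row))
    low = t_row < mean
    high = t_row > mean
    if low.sum() == 0 or high.sum() == 0:
        raise DegenerateInputError(
            f"cannot split samples at the mean of {target}: "
            f"{int(low.sum())} low / {int(high.sum())} high"
        )
    out = {}
    for g in neighbors:
        row = expr.row(g)
        out[g] = float(np.nanmean(row[low]) - np.nanmean(row[high]))
    return out


def combination_count(n_genes: int, grnas_per_gene: int) -> int:
    """Number of guide-pair constructs: (grnas_per_gene * n_genes)^2 / 2."""
    if n_genes <= 0 or grnas_per_gene <= 0:
        raise InputError("gene and gRNA counts must be positive")
    exact = (grnas_per_gene * n_genes) ** 2 / 2
    count = int(exact)
    if count != exact:
        log.warning("combination count %.1f is not integral; truncating", exact)
    return count
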