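"""Per-sample variant: rank target pairs for one cell line.

Node weights come from that single line's essentiality vector and are kept
fixed through conditional scoring; only the background expression panel is
subsampled when modelling the first-target knockdown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import ClusterAssignment
from .errors import InputError
from .io import EssentialityTable, ExpressionMatrix, PPIEdgeList, TargetList
from .network import build_network, correlation_affinity
from .pairs import PairContext, PairScore, rank_all_pairs
from .scoring import WalkConfig


@dataclass
class SingleSampleContext:
    line_id: str
    node_weights: np.ndarray  # aligned with background_expr gene order later
    background_expr: ExpressionMatrix
    ess: EssentialityTable


def make_single_sample_context(
    ess: EssentialityTable, line_id: str, background_expr: ExpressionMatrix
) -> SingleSampleContext:
    if line_id not in ess.cell_lines:
        raise InputError(f"cell line {line_id!r} not in essentiality table")
    col = ess.cell_lines.index(line_id)
    return SingleSampleContext(
        line_id=line_id,
        node_weights=ess.values[:, col].copy(),
        background_expr=background_expr,
        ess=ess,
    )


def dscni_rank_pairs(
    ctx: SingleSampleContext,
    targets: TargetList,
    skeleton: PPIEdgeList,
    assign: ClusterAssignment | None,
    genes,
    scheme: str = "diffusion",
    scope: str = "local",
    walk: WalkConfig | None = None,
    diffusion_ratio: bool = False,
    min_samples: int = 3,
) -> list[PairScore]:
    """Rank all target pairs for one cell line.

    Identical to the cohort-level ranking except that node weights are the
    single line's essentiality values and the essentiality source is never
    subsampled, so conditional scores differ from marginals only through the
    re-estimated edge correlations.
    """
    genes = list(genes)
    ess_line = EssentialityTable(
        genes=list(ctx.ess.genes),
        cell_lines=[ctx.line_id],
        values=ctx.ess.values[:, [ctx.ess.cell_lines.index(ctx.line_id)]],
    )
    S = correlation_affinity(ctx.background_expr, skeleton, genes)
    g_idx = [ess_line.genes.index(g) for g in genes]
    w = ess_line.values[g_idx, 0]
    net_c = build_network(S, w, kind="cellline", genes=genes)
    pair_ctx = PairContext(
        expr_c=ctx.background_expr,
        ess=ess_line,
        skeleton=skeleton,
        net_c=net_c,
        assign=assign,
        scheme=scheme,
        scope=scope,
        walk=walk,
        diffusion_ratio=diffusion_ratio,
        min_samples=min_samples,
        subsample_essentiality=False,
    )
    return rank_all_pairs(targets, pair_ctx)
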