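"""Synthetic datasets with planted structure for every pipeline stage.

Expression follows a block factor model: gene g in block b has

    x_g = sqrt(rho_b) * global + sqrt(rho_w - rho_b) * factor_b + sqrt(1 - rho_w) * noise

so within-block correlation is ~rho_w and between-block ~rho_b. Tumor means
are shifted by per-gene fold-change effects; essentiality values are drawn
around per-gene effects. Synthetic-lethal pairs (x, y) are planted by
giving both genes a shared per-line essentiality factor: their marginal
means are untouched, but in the cell lines where x is most essential
(below its own mean) y's conditional essentiality is shifted strongly
negative, and symmetrically - exactly the conditional signal the knockdown
subsampling is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .io import (
    EssentialityTable,
    ExpressionMatrix,
    PPIEdgeList,
    SLPairTable,
    TargetList,
    write_essentiality,
    write_expression,
    write_ppi,
    write_sl_pairs,
    write_targets,
)


@dataclass
class GeneratorSpec:
    n_genes: int = 30
    n_clusters: int = 3
    n_tumor: int = 100
    n_normal: int = 100
    n_cellline: int = 100   # expression samples for the cell-line panel
    n_lines: int = 20       # essentiality screens
    within_block_corr: float = 0.7
    between_block_corr: float = 0.0
    baseline_expression: float = 5.0
    baseline_fold_change: float = 1.0
    fold_change_effects: dict[str, float] = field(default_factory=dict)
    essentiality_base: float = -0.5
    essentiality_sd: float = 0.3
    essentiality_effects: dict[str, float] = field(default_factory=dict)
    planted_sl_pairs: list[tuple[str, str]] = field(default_factory=list)
    sl_effect: float = -4.0
    within_edge_density: float = 0.6
    between_edge_density: float = 0.0
    n_target_genes: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_genes % self.n_clusters != 0:
            raise InputError(
                f"n_genes={self.n_genes} not divisible by n_clusters={self.n_clusters}"
            )
        for name in ("within_block_corr", "between_block_corr"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [-1, 1]")
        if self.between_block_corr > self.within_block_corr:
            raise InputError("between-block correlation exceeds within-block")
        for name in ("within_edge_density", "between_edge_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [0, 1]")
        known = set(self.gene_names())
        for g in list(self.fold_change_effects) + list(self.essentiality_effects):
            if g not in known:
                raise InputError(f"effect on unknown gene {g!r}")
        for x, y in self.planted_sl_pairs:
            if x not in known or y not in known:
                raise InputError(f"planted SL pair ({x}, {y}) uses unknown genes")
            if x == y:
                raise InputError("planted SL pair with identical genes")

    def gene_names(self) -> list[str]:
        width = max(3, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def block_of(self) -> dict[str, int]:
        per = self.n_genes // self.n_clusters
        return {g: i // per + 1 for i, g in enumerate(self.gene_names())}


@dataclass
class SyntheticDataset:
    tumor: ExpressionMatrix
    normal: ExpressionMatrix
    cellline: ExpressionMatrix
    essentiality: EssentialityTable
    ppi: PPIEdgeList
    targets: TargetList
    sl_truth: SLPairTable
    block_labels: dict[str, int]


def _block_expression(
    rng: np.random.Generator,
    genes: list[str],
    blocks: dict[str, int],
    n_samples: int,
    rho_w: float,
    rho_b: float,
) -> np.ndarray:
    n_blocks = max(blocks.values())
    g_factor = rng.standard_normal(n_samples)
    b_factor = rng.standard_normal((n_blocks, n_samples))
    noise = rng.standard_normal((len(genes), n_samples))
    load_g = np.sqrt(max(rho_b, 0.0))
    load_b = np.sqrt(max(rho_w - rho_b, 0.0))
    load_e = np.sqrt(max(1.0 - rho_w, 0.0))
    X = np.empty((len(genes), n_samples))
    for i, g in enumerate(genes):
        X[i] = load_g * g_factor + load_b * b_factor[blocks[g] - 1] + load_e * noise[i]
    return X


def _block_edges(
    rng: np.random.Generator,
    genes: list[str],
    blocks: dict[str, int],
    d_within: float,
    d_between: float,
) -> list[tuple[str, str, float]]:
    edges = []
    n = len(genes)
    # spanning path inside each block guarantees within-block connectivity
    for b in range(1, max(blocks.values()) + 1):
        members = [g for g in genes if blocks[g] == b]
        for u, v in zip(members, members[1:]):
            edges.append((u, v))
    have = {frozenset(e) for e in edges}
    for i in range(n):
        for j in range(i + 1, n):
            u, v = genes[i], genes[j]
            if frozenset((u, v)) in have:
                continue
            dens = d_within if blocks[u] == blocks[v] else d_between
            if rng.random() < dens:
                edges.append((u, v))
    scores = rng.integers(600, 1000, size=len(edges))
    return [(u, v, float(s)) for (u, v), s in zip(edges, scores)]


def generate_dataset(spec: GeneratorSpec) -> SyntheticDataset:
    """Generate the full input bundle; bit-reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names()
    blocks = spec.block_of()

    def expr(n_samples: int, prefix: str, mean_shift: np.ndarray, condition: str):
        X = _block_expression(
            rng, genes, blocks, n_samples,
            spec.within_block_corr, spec.between_block_corr,
        )
        X = X + spec.baseline_expression + mean_shift[:, None]
        return ExpressionMatrix(
            genes=list(genes),
            samples=[f"{prefix}{i + 1:03d}" for i in range(n_samples)],
            values=X,
            condition=condition,
        )

    fc = np.array(
        [spec.baseline_fold_change + spec.fold_change_effects.get(g, 0.0) for g in genes]
    )
    zero = np.zeros(len(genes))
    tumor = expr(spec.n_tumor, "T", fc, "tumor")
    normal = expr(spec.n_normal, "N", zero, "normal")
    cellline = expr(spec.n_cellline, "C", zero, "cellline")

    ess_mean = np.array(
        [spec.essentiality_base + spec.essentiality_effects.get(g, 0.0) for g in genes]
    )
    E = ess_mean[:, None] + spec.essentiality_sd * rng.standard_normal(
        (len(genes), spec.n_lines)
    )
    gi = {g: i for i, g in enumerate(genes)}
    # plant SL pairs via a shared zero-mean per-line factor; loading chosen so
    # the conditional mean in partner-low lines shifts by about sl_effect/2
    loading = abs(spec.sl_effect) / 2.0
    for x, y in spec.planted_sl_pairs:
        factor = rng.standard_normal(spec.n_lines)
        E[gi[x]] += loading * factor
        E[gi[y]] += loading * factor
    lines = [f"LINE{i + 1:02d}" for i in range(spec.n_lines)]
    essentiality = EssentialityTable(genes=list(genes), cell_lines=lines, values=E)

    ppi = PPIEdgeList(
        edges=_block_edges(
            rng, genes, blocks, spec.within_edge_density, spec.between_edge_density
        )
    )

    planted_genes = sorted({g for pair in spec.planted_sl_pairs for g in pair})
    pool = [g for g in genes if g not in planted_genes]
    n_extra = max(0, spec.n_target_genes - len(planted_genes))
    extra = sorted(
        rng.choice(pool, size=min(n_extra, len(pool)), replace=False).tolist()
    )
    target_genes = planted_genes + extra
    targets = TargetList(
        entries={f"D{i + 1:03d}": {g} for i, g in enumerate(target_genes)}
    )

    sl_truth = SLPairTable(
        pairs=[(x, y, 1.0) for x, y in spec.planted_sl_pairs]
    )
    return SyntheticDataset(
        tumor=tumor,
        normal=normal,
        cellline=cellline,
        essentiality=essentiality,
        ppi=ppi,
        targets=targets,
        sl_truth=sl_truth,
        block_labels=blocks,
    )


DATASET_FILES = {
    "tumor": "tumor_expr.tsv",
    "normal": "normal_expr.tsv",
    "cellline": "cellline_expr.tsv",
    "essentiality": "essentiality.tsv",
    "ppi": "ppi.tsv",
    "targets": "targets.tsv",
    "sl_truth": "sl_pairs.tsv",
}


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Emit the bundle as the plain-text formats the readers consume."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_expression(ds.tumor, os.path.join(outdir, DATASET_FILES["tumor"]))
    write_expression(ds.normal, os.path.join(outdir, DATASET_FILES["normal"]))
    write_expression(ds.cellline, os.path.join(outdir, DATASET_FILES["cellline"]))
    write_essentiality(ds.essentiality, os.path.join(outdir, DATASET_FILES["essentiality"]))
    write_ppi(ds.ppi, os.path.join(outdir, DATASET_FILES["ppi"]))
    write_targets(ds.targets, os.path.join(outdir, DATASET_FILES["targets"]))
    write_sl_pairs(ds.sl_truth, os.path.join(outdir, DATASET_FILES["sl_truth"]))
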