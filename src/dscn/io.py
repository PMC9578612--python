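"""Readers, writers and validated container types for the external table formats.

All gene and drug identifiers are uppercase-normalised on input so that
cross-file joins are plain string-set intersections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, InputError

log = logging.getLogger(__name__)

EXPRESSION_CONDITIONS = ("tumor", "normal", "cellline")


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_numeric_table(path, what: str) -> pd.DataFrame:
    """Read a genes-by-columns table: first column identifiers, header row labels.

    Non-numeric cells raise :class:`FormatError` naming the offending
    row/column; genuinely empty cells become NaN.
    """
    sep = _sniff_sep(path)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {what} table {path}: {exc}") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise InputError(f"{what} table {path} is empty")
    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].tolist()
        raise FormatError(f"duplicate column ids in {what} table {path}: {dups}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    nonblank = raw.notna() & raw.map(lambda v: str(v).strip() != "")
    bad = values.isna() & nonblank
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell in {what} table {path} at row "
            f"'{raw.index[r]}', column '{raw.columns[c]}': {raw.iat[r, c]!r}"
        )
    values.index = values.index.astype(str).str.strip().str.upper()
    values.columns = values.columns.astype(str).str.strip()
    return values


def _collapse_duplicate_rows(df: pd.DataFrame, what: str) -> pd.DataFrame:
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        log.warning("collapsing %d duplicated gene rows in %s by mean: %s",
                    len(dups), what, dups[:10])
        df = df.groupby(level=0, sort=False).mean()
    return df


@dataclass
class ExpressionMatrix:
    """A gene x sample matrix of log2-scale expression values."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    condition: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.condition not in EXPRESSION_CONDITIONS:
            raise InputError(f"unknown expression condition {self.condition!r}")
        if len(set(self.genes)) != len(self.genes):
            raise InputError("duplicate gene symbols in expression matrix")
        if len(set(self.samples)) != len(self.samples):
            raise InputError("duplicate sample ids in expression matrix")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise InputError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.values.size == 0:
            raise InputError("empty expression matrix")
        finite_per_row = np.isfinite(self.values).sum(axis=1)
        if (finite_per_row == 0).any():
            bad = [g for g, n in zip(self.genes, finite_per_row) if n == 0]
            raise InputError(f"expression rows with no finite value: {bad[:10]}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise InputError(f"gene {gene!r} absent from expression matrix") from None

    def subset_samples(self, samples) -> "ExpressionMatrix":
        idx = [self.samples.index(s) for s in samples]
        return ExpressionMatrix(
            genes=list(self.genes),
            samples=list(samples),
            values=self.values[:, idx],
            condition=self.condition,
        )


@dataclass
class EssentialityTable:
    """Gene x cell-line log2 fold changes of cell count after knockout.

    Values are assumed already log2-transformed; more negative = more
    essential.
    """

    genes: list[str]
    cell_lines: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise InputError("duplicate gene symbols in essentiality table")
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise InputError("duplicate cell-line ids in essentiality table")
        if self.values.shape != (len(self.genes), len(self.cell_lines)):
            raise InputError("essentiality matrix dimensions do not match labels")

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise InputError(f"gene {gene!r} absent from essentiality table") from None


@dataclass
class PPIEdgeList:
    """Undirected protein-protein edges with non-negative confidence scores.

    No self-loops; unordered duplicates collapsed keeping the maximum score.
    """

    edges: list[tuple[str, str, float]]

    def __post_init__(self):
        seen: dict[frozenset, float] = {}
        for a, b, s in self.edges:
            if a == b:
                continue
            if s < 0:
                raise InputError(f"negative PPI score for edge ({a}, {b}): {s}")
            key = frozenset((a, b))
            seen[key] = max(seen.get(key, -np.inf), float(s))
        self.edges = sorted(
            (tuple(sorted(k)) + (v,)) for k, v in seen.items()
        )
        self.edges = [(a, b, s) for a, b, s in self.edges]

    @property
    def nodes(self) -> set[str]:
        out = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return out

    def edge_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b, _ in self.edges}


@dataclass
class TargetList:
    """Mapping drug id -> set of target gene symbols."""

    entries: dict[str, set[str]]

    def __post_init__(self):
        norm = {}
        for drug, genes in self.entries.items():
            genes = {str(g).upper() for g in genes}
            if not genes:
                raise InputError(f"drug {drug!r} has an empty target set")
            norm[str(drug)] = genes
        self.entries = norm

    @property
    def all_genes(self) -> set[str]:
        out = set()
        for genes in self.entries.values():
            out |= genes
        return out


@dataclass
class SLPairTable:
    """Known synthetic-lethal gene pairs (unordered) with a score."""

    pairs: list[tuple[str, str, float]]

    def __post_init__(self):
        seen = {}
        for a, b, s in self.pairs:
            a, b = str(a).upper(), str(b).upper()
            if a == b:
                raise InputError(f"self-pair {a!r} in SL table")
            seen[frozenset((a, b))] = float(s)
        self.pairs = [tuple(sorted(k)) + (v,) for k, v in sorted(seen.items(), key=lambda kv: sorted(kv[0]))]
        self.pairs = [(a, b, s) for a, b, s in self.pairs]

    def pair_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b, _ in self.pairs}


@dataclass
class DrugComboTable:
    """Drug-combination screening records: (drugA, drugB, cell line, Bliss score)."""

    records: list[tuple[str, str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        out = []
        for a, b, line, bliss in self.records:
            if a == b:
                raise InputError(f"self-combination {a!r} in drug-combo table")
            bliss = float(bliss)
            if not np.isfinite(bliss):
                raise InputError(f"non-finite Bliss score for ({a}, {b}, {line})")
            out.append((str(a), str(b), str(line), bliss))
        self.records = out


# ---------------------------------------------------------------------------
# readers


def read_expression(path, condition: str) -> ExpressionMatrix:
    """Read a TSV/CSV expression table (genes as rows, samples as columns).

    Duplicate gene rows are collapsed by mean with a logged warning.
    """
    df = _collapse_duplicate_rows(_read_numeric_table(path, "expression"), f"{path}")
    return ExpressionMatrix(
        genes=df.index.tolist(),
        samples=df.columns.tolist(),
        values=df.to_numpy(dtype=float),
        condition=condition,
    )


def read_essentiality(path) -> EssentialityTable:
    df = _collapse_duplicate_rows(_read_numeric_table(path, "essentiality"), f"{path}")
    return EssentialityTable(
        genes=df.index.tolist(),
        cell_lines=df.columns.tolist(),
        values=df.to_numpy(dtype=float),
    )


def read_ppi(path, score_min: float = 400.0) -> PPIEdgeList:
    """Read a STRING-style edge list: protein1 protein2 combined_score.

    Keeps edges with score >= ``score_min``; drops self loops; collapses
    unordered duplicates keeping the maximum score. A header line is
    detected by a non-numeric third column.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                score = float(parts[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise FormatError(
                    f"{path}:{lineno}: non-numeric combined_score {parts[2]!r}"
                ) from None
            a, b = parts[0].upper(), parts[1].upper()
            if a == b:
                continue
            if score >= score_min:
                edges.append((a, b, score))
    if not edges:
        raise InputError(f"no PPI edge in {path} survives score_min={score_min}")
    return PPIEdgeList(edges=edges)


def read_targets(path) -> TargetList:
    """Read a two-column (drug_id, gene) map; repeated drug ids accumulate."""
    entries: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t") if "\t" in line else line.split(",")
            parts = [p.strip() for p in parts if p.strip()]
            if not parts:
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected drug_id<TAB>gene")
            if lineno == 1 and parts[0].lower() in ("drug", "drug_id", "drugid"):
                continue
            entries.setdefault(parts[0], set()).add(parts[1].upper())
    if not entries:
        raise InputError(f"no drug-target entries in {path}")
    return TargetList(entries=entries)


def read_sl_pairs(path) -> SLPairTable:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected columns geneA, geneB, score")
    pairs = [(str(r[0]), str(r[1]), float(r[2])) for r in df.itertuples(index=False)]
    return SLPairTable(pairs=pairs)


def read_drug_combos(path) -> DrugComboTable:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected columns drugA, drugB, cell_line, bliss")
    recs = [(str(r[0]), str(r[1]), str(r[2]), float(r[3])) for r in df.itertuples(index=False)]
    return DrugComboTable(records=recs)


# ---------------------------------------------------------------------------
# writers


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.samples)
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.12g")


def write_essentiality(table: EssentialityTable, path) -> None:
    df = pd.DataFrame(table.values, index=table.genes, columns=table.cell_lines)
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.12g")


def write_ppi(ppi: PPIEdgeList, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, s in ppi.edges:
            fh.write(f"{a}\t{b}\t{s:g}\n")


def write_targets(targets: TargetList, path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tgene\n")
        for drug in sorted(targets.entries):
            for gene in sorted(targets.entries[drug]):
                fh.write(f"{drug}\t{gene}\n")


def write_sl_pairs(table: SLPairTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tsl_score\n")
        for a, b, s in table.pairs:
            fh.write(f"{a}\t{b}\t{s:g}\n")


PAIR_RANKING_COLUMNS = (
    "gene1", "gene2", "IS_T1", "IS_T2_given_T1", "IS_pair", "synergy_flag",
)


def write_pair_ranking(pairs, path) -> None:
    """Write scored pairs as TSV, ascending by combined score.

    Ties on the combined score break lexicographically on (gene1, gene2)
    so output is deterministic.
    """
    rows = sorted(pairs, key=lambda p: (p.is_pair, p.t1, p.t2))
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_RANKING_COLUMNS) + "\n")
        for p in rows:
            fh.write(
                f"{p.t1}\t{p.t2}\t{p.is_t1:.6f}\t{p.is_t2_given_t1:.6f}\t"
                f"{p.is_pair:.6f}\t{int(p.synergy)}\n"
            )
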