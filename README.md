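# dscn

Double-target (synthetic-lethal) combination selection from tumor-tissue
expression, cell-line expression and CRISPR gene-essentiality data on a
shared protein-protein interaction (PPI) skeleton.

The pipeline:

1. **Network construction** — tissue network `G_t` (edges: pairwise Pearson
   correlations in tumor samples restricted to PPI edges; nodes: tumor vs
   normal log2 fold changes) and cell-line network `G_c` (edges: cell-line
   expression correlations; nodes: mean log2 essentiality).
2. **Laplacians** — `L = D - S` plus a row normalization in which each
   connected row's absolute off-diagonal sum equals its absolute diagonal.
3. **Spectral clustering** of the tissue Laplacian with Hartigan-guided
   K-means (at most 10 clusters); labels mapped onto the cell-line network
   by shared gene names.
4. **Impact scoring** of a first target under three schemes — most-probable
   path, seeded random walk (2n steps), deterministic BFS-tier diffusion —
   on the global network or the target's local cluster subnetwork.
5. **Knockdown subsampling** — samples/lines with the first target at or
   above its mean are removed, the cell-line network is rebuilt, and the
   second target re-scored conditionally.
6. **Pair ranking** — `IS(T1,T2) = IS(T1) + IS(T2|T1)` evaluated for both
   orders (the smaller kept); a pair is synergistic when the combined score
   beats the sum of the marginals.

Additional components: per-cell-line scoring with a fixed single-line
essentiality vector (`dscn dscni`), tissue/cell-line subnetwork distance
diagnostics (`dscn similarity`), a Bliss-threshold drug-synergy association
analysis with a 2x2 chi-square/odds-ratio summary (`dscn assoc`), and a
synthetic-data generator with planted clusters and planted SL pairs
(`dscn simulate`).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence on all connected graphs of up to 5 nodes, Laplacian row
invariants, planted-structure recovery, score algebra, and the published
contingency-table statistics).

## CLI

```sh
# generate a synthetic bundle with planted structure
dscn simulate --spec spec.yaml --seed 1 --out data/

# full ranking pipeline (writes pairs.tsv, clusters.tsv,
# subnet_distance.tsv and manifest.json next to --out)
dscn rank \
  --tissue-expr data/tumor_expr.tsv --normal-expr data/normal_expr.tsv \
  --cellline-expr data/cellline_expr.tsv --essentiality data/essentiality.tsv \
  --ppi data/ppi.tsv --targets data/targets.tsv \
  --scheme diffusion --scope local --seed 1 --out pairs.tsv

# per-cell-line variant
dscn dscni --line LINE01 ... --out pairs_line.tsv

# drug-synergy association against a ranking
dscn assoc --combos drugcomb.tsv --pairs pairs.tsv --targets targets.tsv \
  --bliss-threshold 0.12
```

Every knob (STRING score cutoff, scheme/scope, Hartigan rule and threshold,
walk steps, Bliss threshold, ...) can be set in a YAML config passed with
`--config`; unknown keys are rejected. Exit codes: 0 ok, 1 input/config
error, 2 internal error.

## Layout

| module | contents |
| --- | --- |
| `dscn.io` | table readers/writers and validated container types |
| `dscn.network` | affinity/node-weight networks, Laplacians, normalization |
| `dscn.cluster` | spectral embedding, Hartigan K selection, cluster mapping |
| `dscn.scoring` | the three impact-score schemes, local/global dispatch |
| `dscn.pairs` | knockdown subsampling, conditional scores, pair ranking |
| `dscn.similarity` | subnetwork trace matching, edge renormalization, distance |
| `dscn.single_sample` | per-cell-line pair ranking |
| `dscn.association` | Bliss classification, 2x2 table, chi-square, odds ratio |
| `dscn.simulate` | planted-structure synthetic data generator |
| `dscn.config`, `dscn.pipeline`, `dscn.cli` | configuration, orchestration, CLI |
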