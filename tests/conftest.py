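import numpy as np
import pytest

from dscn.io import EssentialityTable, ExpressionMatrix, PPIEdgeList
from dscn.network import build_network


@pytest.fixture
def toy_net():
    """4-node path A-B-C-D with mixed-sign weights used across scoring tests."""
    genes = ["A", "B", "C", "D"]
    S = np.zeros((4, 4))
    S[0, 1] = S[1, 0] = 0.5
    S[1, 2] = S[2, 1] = -0.4
    S[2, 3] = S[3, 2] = 0.8
    w = np.array([-2.0, 2.0, -1.0, 0.5])
    return build_network(S, w, kind="cellline", genes=genes)


@pytest.fixture
def expr_tsv(tmp_path):
    """Write a small expression TSV and return its path."""

    def _write(genes, samples, values, name="expr.tsv"):
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write("gene\t" + "\t".join(samples) + "\n")
            for g, row in zip(genes, values):
                fh.write(g + "\t" + "\t".join(str(v) for v in row) + "\n")
        return path

    return _write


def make_expression(genes, values, condition="cellline", prefix="s"):
    values = np.asarray(values, dtype=float)
    samples = [f"{prefix}{i + 1}" for i in range(values.shape[1])]
    return ExpressionMatrix(genes=list(genes), samples=samples,
                            values=values, condition=condition)


def make_essentiality(genes, values, prefix="L"):
    values = np.asarray(values, dtype=float)
    lines = [f"{prefix}{i + 1}" for i in range(values.shape[1])]
    return EssentialityTable(genes=list(genes), cell_lines=lines, values=values)


def make_ppi(pairs, score=900.0):
    return PPIEdgeList(edges=[(a, b, score) for a, b in pairs])
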