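import numpy as np
import pandas as pd
import pytest

from armonize import MethodCallTable, ProfileMatrix


@pytest.fixture
def toy_tables():
    """Three small method tables over partially overlapping gene sets."""

    def make(name, genes, lfc, q):
        records = pd.DataFrame(
            {"log2fc": lfc, "pvalue": [v / 2 for v in q], "qvalue": q},
            index=pd.Index(genes, name="gene_id"),
        )
        return MethodCallTable(method_name=name, records=records)

    a = make("A", ["g1", "g2", "g3", "g4"], [2.0, -1.5, 0.2, 3.0], [0.01, 0.02, 0.8, 0.001])
    b = make("B", ["g2", "g3", "g4", "g5"], [-1.2, 0.1, 2.5, -2.0], [0.03, 0.9, 0.004, 0.01])
    c = make("C", ["g1", "g3", "g5"], [1.8, -0.1, -1.7], [0.02, 0.7, 0.04])
    return [a, b, c]


@pytest.fixture
def linear_matrix():
    """5-method matrix where method E is a near-exact linear combination:
    E = 2*A - B + 0.5 plus tiny noise, others independent noise."""
    rng = np.random.default_rng(42)
    n = 300
    genes = [f"g{i}" for i in range(n)]
    a = rng.normal(0, 1, n)
    b = rng.normal(0, 1, n)
    c = rng.normal(0, 1, n)
    d = rng.normal(0, 1, n)
    e = 2 * a - b + 0.5 + rng.normal(0, 0.01, n)
    data = pd.DataFrame(
        {"A": a, "B": b, "C": c, "D": d, "E": e},
        index=pd.Index(genes, name="gene_id"),
    )
    return ProfileMatrix(data)
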