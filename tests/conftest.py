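import numpy as np
import pandas as pd
import pytest

from whorlspec import SimConfig, simulate_expression
from whorlspec.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def small_sim():
    """Small canalized two-organ simulation shared across tests."""
    config = SimConfig(n_genes=300, organs=("sepal", "petal", "stamen"),
                       cultivars=("wild",), n_replicates=3, seed=42)
    matrix, truth = simulate_expression(config)
    return config, matrix, truth


def make_matrix(values: dict[str, list[float]], lengths: list[float],
                organs: list[str] | None = None, unit: str = "counts",
                cultivar: str = "wild") -> ExpressionMatrix:
    """Hand-built ExpressionMatrix helper for worked examples."""
    df = pd.DataFrame(values)
    df.index = [f"g{i}" for i in range(len(df))]
    samples = pd.DataFrame({
        "organ": organs if organs is not None else list(values),
        "cultivar": cultivar,
        "replicate": range(1, len(values) + 1),
    }, index=list(values))
    return ExpressionMatrix(values=df,
                            lengths=pd.Series(lengths, index=df.index),
                            samples=samples, unit=unit)


@pytest.fixture
def tiny_counts():
    """Three genes, two samples, column sums 1e6 and 2e6 (RPKM worked values)."""
    return make_matrix(
        {"s1": [10, 999990, 0], "s2": [0, 1999995, 5]},
        lengths=[1000, 2000, 500],
        organs=["sepal", "petal"],
    )
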