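import numpy as np
import pandas as pd
import pytest

from depath.matrix_io import DesignTable, ExpressionMatrix
from depath.simulate import SimulationSpec, simulate_counts


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    """3 genes x 4 samples of integer counts."""
    data = pd.DataFrame(
        {
            "s1": [10.0, 0.0, 5.0],
            "s2": [12.0, 1.0, 5.0],
            "s3": [8.0, 0.0, 5.0],
            "s4": [11.0, 2.0, 5.0],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return ExpressionMatrix(data, "counts")


@pytest.fixture
def factorial_design() -> DesignTable:
    """2x2 factorial: genotype (wt/null) x treatment (mock/IR)."""
    data = pd.DataFrame(
        {
            "p53": ["wt", "wt", "null", "null"],
            "Treatment": ["mock", "IR", "mock", "IR"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    return DesignTable(data)


@pytest.fixture(scope="session")
def simulated():
    """A well-powered two-group NB dataset with 5% planted DE genes."""
    spec = SimulationSpec(n_genes=2000, n_samples_per_group=5, seed=11)
    matrix, design, truth = simulate_counts(spec)
    return matrix, design, truth


@pytest.fixture(scope="session")
def transformed(simulated):
    from depath.preprocess import filter_low_expression, transform_counts

    matrix, design, truth = simulated
    filtered, _ = filter_low_expression(matrix)
    return transform_counts(filtered), design, truth


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
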