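import numpy as np
import pandas as pd
import pytest

from drivernet.datatypes import ExpressionMatrix
from drivernet.simulate import SimulationConfig, TrueNetwork, generate_true_dag


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """Small but structured generator configuration for unit tests."""
    return SimulationConfig(
        n_genes=20,
        n_cohorts=2,
        n_control=80,
        n_disease=80,
        regulator_out_degree=5,
        knockout_n=40,
        seed=11,
    )


@pytest.fixture
def small_truth(small_config):
    return generate_true_dag(small_config)


@pytest.fixture
def chain_truth():
    """Hand-built chain a -> b -> c with known coefficients."""
    return TrueNetwork(
        genes=["a", "b", "c"],
        edges={("a", "b"): 0.8, ("b", "c"): 0.5},
        regulator="a",
        sigma={"a": 1.0, "b": 1.0, "c": 1.0},
        eqtl={},
        module={"a", "b", "c"},
    )


def make_expression(values: np.ndarray, genes=None, samples=None,
                    value_kind="residual", dataset="test") -> ExpressionMatrix:
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), value_kind, dataset
    )
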