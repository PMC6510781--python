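import numpy as np
import pandas as pd
import pytest

from tispec.expression import ExpressionMatrix, double_z, specificity_profile
from tispec.simulate import SimConfig, gen_expression


@pytest.fixture(scope="session")
def desk_config() -> SimConfig:
    """Desk-scale study conditions: 2,000 genes x 30 tissues, 400-node
    network, default rates otherwise."""
    return SimConfig(seed=11, n_genes=2_000, n_tissues=30, network_nodes=400)


@pytest.fixture(scope="session")
def desk_expression(desk_config):
    return gen_expression(desk_config)


@pytest.fixture(scope="session")
def desk_calls(desk_expression):
    expr, _ = desk_expression
    return specificity_profile(double_z(expr))


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 3 tissues with two clear single-tissue peaks and one
    flat gene."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[10.0, 1.0, 1.0], [1.0, 10.0, 1.0], [2.0, 2.0, 2.0]],
            index=["g1", "g2", "g3"],
            columns=["A", "B", "C"],
        )
    )


def random_expression(rng: np.random.Generator, n_genes: int, n_tissues: int):
    values = rng.lognormal(1.0, 1.0, (n_genes, n_tissues))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"t{j}" for j in range(n_tissues)],
        )
    )
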