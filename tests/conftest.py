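import numpy as np
import pytest

from bsmselect import ExpressionDataset, SimulationSpec, simulate_expression


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """3 genes x 6 samples; gene 1 separates the classes, gene 3 is flat-ish."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 3.0, 4.0, 5.0],   # shifted between groups
            [5.0, 4.0, 3.0, 3.0, 2.0, 1.0],   # anti-shifted
            [2.0, 2.1, 1.9, 2.0, 2.1, 1.9],   # uninformative
        ]
    )
    return ExpressionDataset(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=[f"s{i}" for i in range(1, 7)],
        values=values,
        labels=np.array([1, 1, 1, -1, -1, -1]),
    )


@pytest.fixture
def small_sim():
    """Small seeded simulated dataset with known informative genes."""
    spec = SimulationSpec(
        N=60, M1=10, M2=10, n_info=6, delta=2.5,
        n_blocks=2, block_size=8, rho=0.6, seed=7,
    )
    ds, info = simulate_expression(spec)
    return ds, info


def random_dataset(rng: np.random.Generator, N: int = 10, M1: int = 4, M2: int = 4):
    values = rng.normal(size=(N, M1 + M2))
    return ExpressionDataset(
        gene_ids=[f"g{i}" for i in range(N)],
        sample_ids=[f"s{m}" for m in range(M1 + M2)],
        values=values,
        labels=np.array([1] * M1 + [-1] * M2),
    )
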