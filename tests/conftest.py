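import numpy as np
import pandas as pd
import pytest

from germomics import (
    ExpressionMatrix,
    SimulationConfig,
    fabricate_annotation,
    germination_grid,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def grid():
    return germination_grid()


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy simulated transcriptome shared by read-only tests."""
    cfg = SimulationConfig(n_genes=300, seed=11)
    matrix, truth = simulate_transcriptome(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def annot300():
    return fabricate_annotation(300, seed=11)


def toy_matrix(grid, columns, ids=("a", "b", "c")):
    """Build a tiny ExpressionMatrix from {(time, rep, channel): values}."""
    frame = pd.DataFrame(
        {col: np.asarray(vals, dtype=float) for col, vals in columns.items()},
        index=list(ids),
    )
    frame.columns = pd.MultiIndex.from_tuples(
        frame.columns, names=["time", "replicate", "channel"]
    )
    return ExpressionMatrix(frame, grid)
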