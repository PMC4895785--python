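import numpy as np
import pandas as pd
import pytest

from metasig import ExpressionStudy, SimulationConfig


@pytest.fixture(scope="session")
def tiny_sim_config() -> SimulationConfig:
    """A downscaled world for fast pipeline-level tests."""
    return SimulationConfig(
        n_genes=300,
        n_pairs=10,
        n_datasets=2,
        n_drugs=60,
        frac_effective_drugs=0.1,
        n_permutations=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


def make_study(diffs: np.ndarray, genes=None) -> ExpressionStudy:
    """Build a paired study whose tumor - normal differences equal ``diffs``."""
    diffs = np.atleast_2d(np.asarray(diffs, float))
    n_genes, n_pairs = diffs.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    pairs = [(f"P{i}", f"P{i}_T", f"P{i}_N") for i in range(n_pairs)]
    cols = {}
    for i, (_, tcol, ncol) in enumerate(pairs):
        cols[tcol] = diffs[:, i]
        cols[ncol] = np.zeros(n_genes)
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return ExpressionStudy(dataset_id="DS0", stage="early", matrix=matrix, pairs=pairs)
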