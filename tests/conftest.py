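import numpy as np
import pytest

from scmetrics.core import AnnotatedMatrix, Embedding
from scmetrics.fixtures import make_count_scenario, make_embedding_scenario


@pytest.fixture(scope="session")
def mixture_scenario():
    """Well-mixed 3-type, 2-batch embedding scenario."""
    return make_embedding_scenario(
        n_cells=450, n_types=3, n_batches=2, batch_shift=0.0, seed=11
    )


@pytest.fixture(scope="session")
def count_matrix():
    """Gamma-Poisson count fixture with cell-cycle-like gene program."""
    return make_count_scenario(n_cells=400, n_genes=250, n_batches=2, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def matrix_from_embedding(emb: Embedding, batch, label) -> AnnotatedMatrix:
    n, d = emb.coords.shape
    return AnnotatedMatrix(
        values=emb.coords,
        cell_ids=[f"cell{i}" for i in range(n)],
        feature_ids=[f"dim{j}" for j in range(d)],
        batch=batch,
        label=label,
    )
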