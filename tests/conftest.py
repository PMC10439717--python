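import numpy as np
import pytest

from lider.io import ExpressionMatrix, LabelSet
from lider.simulate import SyntheticSpec, generate_dataset


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    return ExpressionMatrix(
        values=rng.normal(size=(5, 4)),
        gene_ids=[f"g{j}" for j in range(4)],
        cell_ids=[f"c{i}" for i in range(5)],
    )


@pytest.fixture
def tiny_labels() -> LabelSet:
    return LabelSet(
        cell_ids=[f"c{i}" for i in range(5)],
        labels=["Tcell", "Bcell", "Tcell", "NK", "Bcell"],
    )


@pytest.fixture(scope="session")
def clustered_dataset():
    """Well-separated 4-type dataset used by several training tests."""
    spec = SyntheticSpec(
        n_cells=400, n_genes=80, n_types=4, latent_dim=8,
        separation=5.0, noise_sd=1.0, dropout_rate=0.1, seed=11,
    )
    return generate_dataset(spec)
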