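import warnings

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

import cellbridge as cb

warnings.filterwarnings("ignore", message=".*batch norm over a single sample.*")


@pytest.fixture(scope="session")
def small_counts():
    """2 batches, 200 cells, 50 genes (seed 7)."""
    return cb.simulate_multibatch(
        cb.SimSpec(n_types=2, n_batches=2, cells_per_type_per_batch=50,
                   n_features=50, seed=7)
    )


@pytest.fixture(scope="session")
def small_scaled(small_counts):
    params = cb.PreprocessParams(
        min_genes_per_cell=5, min_cells_per_gene=1, n_top_features=20
    )
    return cb.preprocess_rna(small_counts, params)


@pytest.fixture(scope="session")
def tiny_trained(small_scaled):
    """A very short training run shared by projection/serialization tests."""
    model, log = cb.fit(
        small_scaled,
        train_cfg=cb.TrainConfig(seed=0, max_iterations=120),
    )
    return model, log, small_scaled


def toy_adata(X, batches, types=None, genes=None):
    X = np.asarray(X, dtype=float)
    obs = pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])])
    obs["batch"] = list(batches)
    if types is not None:
        obs["cell_type"] = list(types)
    var = pd.DataFrame(
        index=genes or [f"g{j}" for j in range(X.shape[1])]
    )
    return AnnData(X=X, obs=obs, var=var)
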