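import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import diffproj as dp

# umap emits benign numba/sklearn warnings under a fixed random_state
warnings.filterwarnings("ignore", message=".*n_jobs value 1.*")


@pytest.fixture
def tiny_counts() -> dp.CountMatrix:
    """4 cells x 3 genes with one mitochondrial gene."""
    values = sp.csr_matrix(
        np.array(
            [
                [2, 3, 0],
                [0, 0, 0],
                [1, 1, 2],
                [5, 0, 5],
            ]
        )
    )
    features = pd.DataFrame(
        {"id": ["g1", "g2", "g3"], "symbol": ["MT-ND1", "ACTB", "GAPDH"]}
    )
    barcodes = np.array([f"bc{i}" for i in range(4)], dtype=object)
    return dp.CountMatrix(values=values, barcodes=barcodes, features=features)


@pytest.fixture(scope="session")
def cluster_sim():
    """Default 5-cluster negative-binomial mixture with planted markers."""
    return dp.simulate_cluster_counts(seed=0)


@pytest.fixture(scope="session")
def cluster_pipeline(cluster_sim):
    """Preprocessed + embedded + clustered 5-cluster mixture."""
    matrix, truth = cluster_sim
    scaled, lognorm, hvg = dp.preprocess_counts(matrix, n_hvg=1000)
    space = dp.fit_dbmap(
        scaled.values, dp.DbmapParams(n_components=30, n_neighbors=15)
    )
    est = dp.SNNGraphClustering(resolution=0.1, seed=0).fit(
        space.structure_components
    )
    return {
        "matrix": matrix,
        "truth": truth,
        "lognorm": lognorm,
        "space": space,
        "clustering": est,
    }


@pytest.fixture(scope="session")
def branching_sim():
    """Default 3-branch negative-binomial lineage (3000 cells x 1500 genes)."""
    return dp.simulate_branching_counts(seed=1)


@pytest.fixture(scope="session")
def branching_pipeline(branching_sim):
    """Preprocessed + embedded + trajectory-fitted branching lineage."""
    matrix, truth = branching_sim
    scaled, lognorm, hvg = dp.preprocess_counts(matrix, n_hvg=1500)
    space = dp.fit_dbmap(
        scaled.values, dp.DbmapParams(n_components=30, n_neighbors=15)
    )
    start = int(np.argmin(truth.pseudotime_true))
    model = dp.TrajectoryModel().fit(space, start_cell=start)
    return {
        "matrix": matrix,
        "truth": truth,
        "lognorm": lognorm,
        "space": space,
        "start": start,
        "model": model,
    }
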