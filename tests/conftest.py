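import numpy as np
import pandas as pd
import pytest

from cellspin.matrix import ExpressionMatrix
from cellspin.synth import SyntheticSpec, make_clustered_counts


@pytest.fixture(scope="session")
def small_clustered():
    """300 cells in 3 types, 1000 genes, fold-10 markers; with truth."""
    spec = SyntheticSpec(
        n_genes=1000, n_cells=300, n_types=3, marker_fold=10,
        markers_per_type=20, seed=2,
    )
    return make_clustered_counts(spec)


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(0)
    counts = rng.poisson(2.0, size=(30, 20))
    return ExpressionMatrix(
        counts,
        [f"g{i}" for i in range(30)],
        [f"c{i}" for i in range(20)],
        pd.DataFrame({"age": rng.choice([11.0, 12.0], 20)},
                     index=[f"c{i}" for i in range(20)]),
    )
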