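import numpy as np
import pytest

import itersig as ig


def make_matrix(values, genes=None, cells=None, groups=None, scale=ig.Scale.LINEAR_TPM):
    """Small helper: build an ExpressionMatrix from a 2-D list/array."""
    values = np.asarray(values, dtype=float)
    n_g, n_c = values.shape
    genes = genes or [f"g{i + 1}" for i in range(n_g)]
    cells = cells or [f"c{j + 1}" for j in range(n_c)]
    groups = groups or {c: "G1" for c in cells}
    return ig.ExpressionMatrix(tuple(genes), tuple(cells), values, scale, groups)


@pytest.fixture(scope="session")
def default_sim():
    """The six-class parameter-recovery benchmark, seed 1."""
    return ig.simulate_single_cell_matrix(ig.default_spec(seed=1))


@pytest.fixture(scope="session")
def default_clustering(default_sim):
    matrix, _ = default_sim
    return ig.iterate(matrix)


@pytest.fixture(scope="session")
def study_sim():
    """The 17-subpopulation study-shaped emulation, seed 1."""
    return ig.simulate_single_cell_matrix(ig.study_spec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
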