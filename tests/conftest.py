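import numpy as np
import pytest
import scipy.sparse as sp

import osteotx as ox


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def tiny_matrix():
    """4 genes x 3 cells with hand-checkable counts."""
    counts = np.array(
        [
            [350, 10, 0],     # Col1a1
            [50, 0, 5],       # Hspa9
            [9500, 940, 80],  # Bg0000
            [100, 50, 15],    # mt-Nd1
        ]
    )
    return ox.CountMatrix(
        sp.csr_matrix(counts),
        ["Col1a1", "Hspa9", "Bg0000", "mt-Nd1"],
        ["c1", "c2", "c3"],
    )


@pytest.fixture
def random_matrix(rng):
    """50 genes x 20 cells of Poisson counts (every cell nonempty)."""
    counts = rng.poisson(3.0, size=(50, 20))
    counts[0] += 1  # guard against a zero-total column
    genes = [f"G{i:03d}" for i in range(50)]
    cells = [f"cell{i:02d}" for i in range(20)]
    return ox.CountMatrix(sp.csr_matrix(counts), genes, cells)


@pytest.fixture(scope="session")
def wt_cells():
    """A moderately sized WT cohort reused by read-only tests."""
    return ox.simulate_cells(
        ox.SimulationSpec(n_cells=800, genotype="WT", seed=11, batch="wtA")
    )


@pytest.fixture(scope="session")
def het_cells():
    return ox.simulate_cells(
        ox.SimulationSpec(n_cells=800, genotype="Het", seed=12, batch="hetA")
    )
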