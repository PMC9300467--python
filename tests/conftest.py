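import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from celltalk import CountMatrix, QCThresholds, SimConfig
from celltalk.simulate import simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 6 types x 300 cells x 1,500 genes with
    planted interactions (log2FC 2), regulons (1 ln-unit target shift) and
    motifs (+0.3 accessibility)."""
    return simulate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_config():
    """A light configuration for structural tests (not powered for recovery)."""
    return SimConfig(
        n_cell_types=4, cells_per_type=60, n_genes=300,
        n_planted_interactions=2, n_decoy_interactions=3,
        n_regulons=2, targets_per_regulon=8,
        n_peaks=120, n_motifs=2, seed=1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def relaxed_qc():
    """QC thresholds scaled to the small fixture's gene count."""
    return QCThresholds(min_genes_per_cell=50, joint_min_counts=50)


def make_counts(array, cell_types=None, gene_ids=None, zones=None):
    """Build a CountMatrix from a dense array for hand-crafted fixtures."""
    array = np.asarray(array)
    n_cells, n_genes = array.shape
    cell_ids = [f"c{i}" for i in range(n_cells)]
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(n_genes)]
    if cell_types is None:
        cell_types = ["T0"] * n_cells
    meta = pd.DataFrame({
        "cell_type": cell_types,
        "sample": "s0",
        "zone": zones if zones is not None else [pd.NA] * n_cells,
    }, index=cell_ids)
    return CountMatrix(counts=sp.csr_matrix(array), cell_ids=cell_ids,
                       gene_ids=gene_ids, cell_meta=meta)


@pytest.fixture
def tiny_counts():
    """3 cells x 4 genes with 5 nonzeros."""
    return make_counts(
        [[1, 0, 2, 0],
         [0, 3, 0, 0],
         [0, 0, 4, 0]],
        cell_types=["A", "A", "B"],
    )
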