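import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scburden.dataset import Dataset, normalize_log
from scburden.simulate import SimConfig, simulate_dataset


def make_dataset(counts, mito_flags=None, ribo_flags=None, cells_extra=None):
    """Dataset from a dense count array (genes x cells) with minimal metadata."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    genes = pd.DataFrame(
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    )
    genes["gene_symbol"] = genes.index
    genes["pct_mito_flag"] = (
        np.zeros(n_genes, bool) if mito_flags is None else np.asarray(mito_flags, bool)
    )
    genes["pct_ribo_flag"] = (
        np.zeros(n_genes, bool) if ribo_flags is None else np.asarray(ribo_flags, bool)
    )
    cells = pd.DataFrame(
        index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id")
    )
    cells["donor_id"] = [f"d{i % 2}" for i in range(n_cells)]
    cells["diagnosis"] = ["control" if i % 2 == 0 else "case" for i in range(n_cells)]
    cells["cell_type"] = "CT0"
    if cells_extra:
        for k, v in cells_extra.items():
            cells[k] = v
    return Dataset(counts=sp.csr_matrix(counts), cells=cells, genes=genes)


@pytest.fixture
def toy_dataset():
    return make_dataset([[2, 0], [0, 0], [0, 1]])


@pytest.fixture(scope="session")
def small_de_dataset():
    """Shared small case-control simulation with true DE structure."""
    cfg = SimConfig(
        n_donors_per_group=5,
        cells_per_donor=100,
        n_cell_types=1,
        n_genes=300,
        frac_de=0.2,
        log2fc_de=1.0,
        seed=7,
    )
    d, truth = simulate_dataset(cfg)
    return normalize_log(d), truth, cfg
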