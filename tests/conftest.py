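import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from convtrace import QCThresholds, SimConfig, simulate_counts, simulate_transgenes
from convtrace.io import GENE_CLASS, MITO_CLASS, TRANSGENE_CLASS


def small_sim_config(**overrides) -> SimConfig:
    """A fast 3-timepoint configuration for unit tests."""
    defaults = dict(
        n_cells_per_timepoint=300,
        timepoints=("D0", "D2", "D7"),
        neuron_fraction_by_timepoint={"D0": 0.0, "D2": 0.3, "D7": 0.6},
        n_genes=400,
        n_extra_markers=15,
        n_clones=15,
        umis_per_barcoded_cell=3.0,
        reads_per_umi=1.5,
        seed=7,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


SMALL_QC = QCThresholds(min_genes=50, max_genes=12000, max_mito_fraction=0.05)


@pytest.fixture(scope="session")
def small_dataset():
    """Counts + transgenes + truth at unit-test scale."""
    cfg = small_sim_config()
    adata, truth = simulate_counts(cfg)
    adata = simulate_transgenes(cfg, adata, truth)
    return cfg, adata, truth


def dense_adata(X, gene_names=None, cell_names=None, classes=None) -> ad.AnnData:
    """Build a small AnnData with a counts layer from a dense array."""
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    genes = list(gene_names) if gene_names is not None else [f"g{i}" for i in range(g)]
    cells = list(cell_names) if cell_names is not None else [f"c{i}" for i in range(n)]
    var = pd.DataFrame(index=genes)
    var["gene_symbol"] = genes
    var["feature_class"] = list(classes) if classes is not None else GENE_CLASS
    adata = ad.AnnData(X=sp.csr_matrix(X), var=var, obs=pd.DataFrame(index=cells))
    adata.layers["counts"] = adata.X.copy()
    return adata


__all__ = [
    "small_sim_config",
    "dense_adata",
    "SMALL_QC",
    "GENE_CLASS",
    "MITO_CLASS",
    "TRANSGENE_CLASS",
]
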