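import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from osnatlas import corematrix
from osnatlas.simdata import SimulationConfig, simulate_atlas


def small_config(seed: int = 0, **kw) -> SimulationConfig:
    """Desk-size paired atlas: 2 sensilla (one with a full-death class),
    ~1,100 cells, 600 genes — enough structure for every stage."""
    defaults = dict(
        n_genes=600,
        n_sensilla=2,
        classes_per_sensillum=(2, 2),
        death_fates={"at1B": "full"},
        cells_per_class_per_phase=50,
        marker_genes_per_class=25,
        time_genes_per_direction=30,
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_atlas():
    return simulate_atlas(small_config(seed=0))


@pytest.fixture(scope="session")
def small_expr(small_atlas):
    ctrl, blocked, cells, truth = small_atlas
    joint = corematrix.integrate_conditions(ctrl, blocked, mode="concat")
    return corematrix.normalize(joint), truth


def make_expr(values: np.ndarray, genes=None, cells=None, target_sum=1e4) -> ad.AnnData:
    """AnnData wrapper around a dense cells x genes value matrix."""
    values = np.asarray(values, float)
    n, g = values.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(g)]
    cells = list(cells) if cells is not None else [f"c{i}" for i in range(n)]
    adata = ad.AnnData(
        X=sparse.csr_matrix(values),
        obs=pd.DataFrame(index=pd.Index(cells, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["target_sum"] = target_sum
    return adata
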