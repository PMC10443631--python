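import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ossa import CellMatrix, SimulationConfig, compute_size_factors, log_normalize, null_cohort
from ossa.io import NormalizedLayer


def make_cohort(counts, regions=None, conditions=None, cell_types=None,
                tissue_classes=None, doublet_scores=None, mito_genes=0,
                samples=None):
    """Build a small validated CellMatrix from a dense count array."""
    counts = np.asarray(counts, dtype=np.int64)
    n, g = counts.shape
    regions = list(regions) if regions is not None else ["region_0"] * n
    conditions = list(conditions) if conditions is not None else ["naive"] * n
    cell_types = list(cell_types) if cell_types is not None else ["type_0"] * n
    tissue_classes = (
        list(tissue_classes) if tissue_classes is not None else ["bone"] * n
    )
    doublet_scores = (
        list(doublet_scores) if doublet_scores is not None else [0.01] * n
    )
    samples = list(samples) if samples is not None else [
        f"{r}_{c}" for r, c in zip(regions, conditions)
    ]
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:04d}" for i in range(n)],
            "region": regions,
            "condition": conditions,
            "cell_type": cell_types,
            "sample_id": samples,
            "tissue_class": tissue_classes,
            "doublet_score": doublet_scores,
        }
    )
    genes = pd.DataFrame(
        {
            "gene_id": [f"mt-g{i:03d}" if i < mito_genes else f"g{i:03d}" for i in range(g)],
            "is_mito": [i < mito_genes for i in range(g)],
        }
    )
    return CellMatrix(sp.csr_matrix(counts), cells, genes).validate()


def layer_from_dense(values, gene_ids=None):
    """Wrap a dense array of log-normalized values as a NormalizedLayer."""
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i:03d}" for i in range(values.shape[1])]
    return NormalizedLayer(
        values=sp.csr_matrix(values),
        size_factors=np.ones(values.shape[0]),
        gene_ids=np.asarray(gene_ids),
    )


def normalized_null_layer(config: SimulationConfig):
    """Simulate a null cohort and log-normalize it with single-cluster size
    factors (the homogeneous-population case)."""
    cohort, truth = null_cohort(config)
    sf = compute_size_factors(cohort, np.zeros(cohort.n_cells, dtype=int))
    return cohort, log_normalize(cohort, sf), truth


def normalize_by_type(cohort):
    """Log-normalize with size-factor pooling clusters set to the annotated
    cell types — the idealized outcome of the clustering step."""
    codes = cohort.cells["cell_type"].astype("category").cat.codes.to_numpy()
    sf = compute_size_factors(cohort, codes)
    return log_normalize(cohort, sf)


@pytest.fixture
def small_cohort():
    rng = np.random.default_rng(11)
    counts = rng.poisson(2.0, size=(30, 12))
    return make_cohort(counts)
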