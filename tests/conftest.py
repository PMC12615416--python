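import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from modscore import (
    BulkSimSpec,
    CellMatrix,
    CountMatrix,
    ImageSimSpec,
    ScSimSpec,
    simulate_bulk,
    simulate_field,
    simulate_sc,
)


@pytest.fixture
def tiny_counts():
    """Hand-built 3-gene, 4-sample count matrix."""
    counts = pd.DataFrame(
        {
            "c1": [10, 10, 100],
            "c2": [12, 8, 90],
            "t1": [40, 10, 110],
            "t2": [38, 12, 95],
        },
        index=["gA", "gB", "gC"],
    )
    return CountMatrix(
        counts=counts,
        gene_lengths=pd.Series([1000, 2000, 1500], index=counts.index),
        condition=pd.Series(
            ["control", "control", "treated", "treated"], index=counts.columns
        ),
    )


def make_cell_matrix(counts_dense, mito_mask, labels=None):
    n_cells, n_genes = counts_dense.shape
    cell_ids = [f"c{i}" for i in range(n_cells)]
    symbols = [f"G{i}" for i in range(n_genes)]
    return CellMatrix(
        counts=sparse.csr_matrix(counts_dense),
        cell_ids=cell_ids,
        gene_symbols=symbols,
        mito_mask=np.asarray(mito_mask, dtype=bool),
        labels=pd.Series(labels, index=cell_ids) if labels is not None else None,
    )


@pytest.fixture(scope="session")
def sc_sim():
    """Default two-population single-cell simulation (no QC outliers)."""
    return simulate_sc(ScSimSpec(seed=7))


@pytest.fixture(scope="session")
def sc_sim_outliers():
    """Single-cell simulation with 10 cells planted per QC-outlier class."""
    frac = 10 / 600
    spec = ScSimSpec(
        seed=11,
        qc_outlier_fractions={
            "low_features": frac,
            "high_features": frac,
            "high_counts": frac,
            "high_mito": frac,
        },
    )
    return simulate_sc(spec)


@pytest.fixture(scope="session")
def field_sim():
    """Noiseless 200-nuclei field with known truth."""
    return simulate_field(ImageSimSpec(seed=5))


@pytest.fixture(scope="session")
def null_bulk_de():
    """NB Wald test on a 2000-gene null simulation (no planted effects)."""
    from modscore import nb_wald_test

    m, _ = simulate_bulk(BulkSimSpec(n_genes=2000, seed=13))
    return nb_wald_test(m)
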