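import numpy as np
import pandas as pd
import pytest

from nkfate import synthdata as sdt
from nkfate.io_qc import CountMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240821)


@pytest.fixture(scope="session")
def small_sim():
    """A compact 3-group synthetic experiment shared by read-only tests."""
    cfg = sdt.default_config(seed=11, n_cells_per_group=300)
    cfg.groups = ("control", "PT-6h", "PT-24h")
    cfg.paradigm_fractions = {
        "control": {"healthy": 1.0},
        "PT-6h": {"intrinsic_apoptosis": 0.7, "healthy": 0.3},
        "PT-24h": {"pyroptosis": 0.7, "healthy": 0.3},
    }
    cfg.hypoxia.group_trend = {"control": 0.0, "PT-6h": 1.2, "PT-24h": 0.4}
    cfg.validate()
    matrix, truth, collection = sdt.simulate_experiment(cfg)
    return cfg, matrix, truth, collection


def expression_from_dense(
    values: np.ndarray,
    genes: list[str] | None = None,
    barcodes: list[str] | None = None,
    meta: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    genes = genes or [f"G{i:03d}" for i in range(g)]
    barcodes = barcodes or [f"C{i:04d}" for i in range(c)]
    if meta is None:
        meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return ExpressionMatrix(
        genes=np.asarray(genes, dtype=object),
        barcodes=np.asarray(barcodes, dtype=object),
        x=values,
        cell_meta=meta,
    )


def counts_from_dense(values, genes=None, barcodes=None, meta=None) -> CountMatrix:
    import scipy.sparse as sp

    values = np.asarray(values)
    g, c = values.shape
    genes = genes or [f"G{i:03d}" for i in range(g)]
    barcodes = barcodes or [f"C{i:04d}" for i in range(c)]
    if meta is None:
        meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return CountMatrix(
        genes=np.asarray(genes, dtype=object),
        barcodes=np.asarray(barcodes, dtype=object),
        counts=sp.csr_matrix(values),
        cell_meta=meta,
    )
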