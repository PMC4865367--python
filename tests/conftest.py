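import numpy as np
import pandas as pd
import pytest

from axialmrg.counts_io import CountMatrix
from axialmrg.synthetic_data import SimConfig, simulate_axis_counts


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration simulation shared across read-only tests."""
    return simulate_axis_counts(SimConfig(seed=0))


@pytest.fixture()
def tiny_cm():
    """3 genes x 2 cells toy count matrix."""
    counts = pd.DataFrame(
        [[1, 2], [3, 4], [5, 6]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["c1", "c2"],
    )
    meta = pd.DataFrame(
        {"region": [1, 2]}, index=pd.Index(["c1", "c2"], name="cell_id")
    )
    return CountMatrix(counts, meta)


def make_expression(values, regions=None, cells=None, genes=None):
    """Build an ExpressionMatrix directly from a value array."""
    from axialmrg.qc_normalize import ExpressionMatrix

    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=cells)
    reg = None
    if regions is not None:
        reg = pd.Series(regions, index=cells)
    return ExpressionMatrix(values=df, regions=reg)
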