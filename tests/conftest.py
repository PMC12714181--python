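import numpy as np
import pandas as pd
import pytest

from degnet.io_formats import ExpressionMatrix, make_metadata
from degnet.synthetic import SimulationConfig


@pytest.fixture
def small_config():
    """Three small cohorts with planted DE genes, desk-scale."""
    return SimulationConfig(
        n_genes=400,
        cohorts=(("A", 8, 8), ("B", 8, 8), ("C", 8, 8)),
        de_fraction=0.1,
        lfc_magnitude=2.0,
        n_reversal=10,
        regulon_size=15,
        seed=11,
    )


@pytest.fixture
def two_group_counts():
    """Deterministic 6-gene, 4+4-sample count matrix with two clear DE genes."""
    rng = np.random.default_rng(5)
    base = rng.integers(50, 200, size=(6, 8)).astype(float)
    base[0, 4:] *= 8  # strong up
    base[1, 4:] = np.maximum(base[1, 4:] / 8, 1)  # strong down
    data = pd.DataFrame(
        np.rint(base),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(8)],
    )
    matrix = ExpressionMatrix(data, "counts")
    meta = make_metadata(
        [(f"s{i}", "X", "healthy" if i < 4 else "tumor") for i in range(8)]
    )
    return matrix, meta
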