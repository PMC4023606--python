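import numpy as np
import pandas as pd
import pytest

from gcabias.quant import CountMatrix, load_rice_pathway_rpkm


@pytest.fixture(scope="session")
def pathway_rpkm() -> pd.DataFrame:
    """Published RPKM table for rice flowering/GA pathway genes (3 parents, 3 F1s)."""
    return load_rice_pathway_rpkm()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240422)


@pytest.fixture()
def small_counts():
    """A tiny two-sample count matrix with unequal library sizes."""
    counts = pd.DataFrame(
        {"A": [10, 0, 100, 0, 5], "B": [20, 40, 100, 0, 10]},
        index=[f"g{i}" for i in range(1, 6)],
    )
    return CountMatrix(counts=counts, lib_sizes=pd.Series({"A": 1e6, "B": 2e6}))
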