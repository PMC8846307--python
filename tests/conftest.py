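import numpy as np
import pandas as pd
import pytest

from refstab.datasets import load_pbmc_cq
from refstab.io import CqMatrix
from refstab.preprocess import relative_quantities


@pytest.fixture(scope="session")
def pbmc():
    """The packaged 30-sample x 10-gene bovine PBMC Cq matrix."""
    return load_pbmc_cq()


@pytest.fixture(scope="session")
def pbmc_rq(pbmc):
    return relative_quantities(pbmc)


@pytest.fixture()
def toy_cq():
    """4 samples x 3 genes, two groups, hand-checkable numbers."""
    data = pd.DataFrame(
        {
            "G1": [20.0, 21.0, 22.0, 20.5],
            "G2": [25.0, 25.5, 26.5, 25.0],
            "G3": [18.0, 19.5, 18.5, 19.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    groups = pd.Series(["a", "a", "b", "b"], index=data.index)
    return CqMatrix(data, groups)


def make_cq(values, groups=None, samples=None, genes=None):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    genes = genes or [f"g{j}" for j in range(k)]
    labels = pd.Series(groups if groups is not None else ["all"] * n, index=samples)
    return CqMatrix(pd.DataFrame(values, index=samples, columns=genes), labels)
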