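import numpy as np
import pandas as pd
import pytest

from renin_gsx import ExpressionMatrix, GeneSetCollection


def make_matrix(values, groups=("baseline", "day5"), row_prefix="G"):
    """ExpressionMatrix from a 2-D array, halving samples into two groups."""
    arr = np.asarray(values, dtype=float)
    n_rows, n_samp = arr.shape
    half = n_samp // 2
    samples = [f"{groups[0]}_{i}" for i in range(half)] + [
        f"{groups[1]}_{i}" for i in range(n_samp - half)
    ]
    gmap = {s: (groups[0] if i < half else groups[1]) for i, s in enumerate(samples)}
    rows = [f"{row_prefix}{i:04d}" for i in range(n_rows)]
    return ExpressionMatrix(pd.DataFrame(arr, index=rows, columns=samples), gmap)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix(rng):
    """50 genes x 4+4 samples, pure noise around gene-specific baselines."""
    base = rng.uniform(6, 12, 50)
    vals = base[:, None] + rng.normal(0, 0.3, (50, 8))
    return make_matrix(vals)


@pytest.fixture
def tiny_catalog():
    return GeneSetCollection.from_dict(
        {
            "SET_A": ["G0001", "G0002", "G0003"],
            "SET_B": ["G0002", "G0003", "G0004", "G0005"],
            "SET_C": ["G0010", "G0011"],
        },
        catalog="OTHER",
    )
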