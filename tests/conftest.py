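import numpy as np
import pandas as pd
import pytest

from epichaos import BinaryMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_matrix(rng):
    """Random 50-feature x 12-cell binary matrix."""
    arr = (rng.random((50, 12)) < 0.4).astype(np.uint8)
    return BinaryMatrix.from_dense(arr)


@pytest.fixture
def toy_features():
    """Two-chromosome coordinate table for the 50-feature toy matrix."""
    chrom = np.repeat(["chr1", "chr2"], 25)
    start = np.tile(np.arange(25) * 1000, 2)
    return pd.DataFrame({"chrom": chrom, "start": start, "end": start + 500})


@pytest.fixture
def toy_grouping(toy_matrix):
    cells = list(toy_matrix.cell_ids)
    return {c: ("g1" if i < 6 else "g2") for i, c in enumerate(cells)}
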