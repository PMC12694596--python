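import numpy as np
import pandas as pd
import pytest

from scvib.data import GenomicInterval, OmicsDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """A 10-cell, 5-gene RNA dataset with covariates and labels."""
    counts = rng.poisson(3.0, size=(10, 5)).astype(float)
    return OmicsDataset(
        matrix=counts,
        feature_ids=[f"gene{i}" for i in range(5)],
        cell_ids=[f"cell{i}" for i in range(10)],
        modality="rna",
        covariates=pd.DataFrame({"batch": ["b0"] * 5 + ["b1"] * 5}),
        cell_type_labels=pd.DataFrame({"cell_type": ["A"] * 5 + ["B"] * 5}),
    )


@pytest.fixture
def random_intervals(rng):
    def make(n, chrom="chr1", span=100_000):
        out = []
        for _ in range(n):
            start = int(rng.integers(0, span))
            end = start + int(rng.integers(50, 2_000))
            out.append(GenomicInterval(chrom, start, end))
        return out

    return make
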