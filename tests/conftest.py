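import numpy as np
import pandas as pd
import pytest

from methylaging.core import MethylationDataset


@pytest.fixture
def tiny_dataset() -> MethylationDataset:
    """Three loci x two samples with one uncovered entry."""
    return MethylationDataset(
        chrom=np.array(["chr1", "chr1", "chr2"], dtype=object),
        pos=np.array([100, 250, 50]),
        sample_ids=["s1", "s2"],
        M=np.array([[3, 5], [0, 2], [7, 0]]),
        N=np.array([[10, 12], [0, 9], [10, 11]]),
    )


@pytest.fixture
def random_dataset() -> MethylationDataset:
    rng = np.random.default_rng(42)
    L, S = 500, 8
    pos = np.sort(rng.choice(np.arange(1, 100_000), size=L, replace=False))
    N = rng.poisson(12, size=(L, S))
    M = rng.binomial(N, rng.uniform(0.05, 0.95, size=(L, 1)))
    return MethylationDataset(
        chrom=np.array(["chr1"] * L, dtype=object), pos=pos,
        sample_ids=[f"s{i}" for i in range(S)], M=M, N=N,
    )


@pytest.fixture
def cohort_table() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    n = 24
    return pd.DataFrame({
        "subject_id": [f"S{i:02d}" for i in range(n)],
        "age": np.linspace(25, 80, n),
        "sex": rng.choice(["F", "M"], size=n),
        "race": rng.choice(["A", "B"], size=n),
        "bmi": rng.normal(27, 3, size=n),
    })
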