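import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hkgscout as h

settings.register_profile("default", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("default")


def make_counts(array, genes=None, samples=None) -> h.CountMatrix:
    arr = np.asarray(array, dtype=np.int64)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return h.CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


@pytest.fixture
def tiny_counts():
    return make_counts([[2, 4], [4, 8], [8, 16]], genes=["a", "b", "c"])


@pytest.fixture(scope="session")
def default_simulation():
    """One full-size simulated study (10,000 genes, 6 groups x 5 samples)."""
    cfg = h.SimulationConfig(seed=2019)
    counts, lengths, lib_sizes, truth = h.simulate_dataset(cfg)
    filtered = h.filter_all_zero_genes(counts)
    return cfg, filtered, lengths, lib_sizes, truth


@pytest.fixture(scope="session")
def random_positive_counts():
    """A bank of seeded random positive count matrices for oracle tests."""
    rng = np.random.default_rng(123)
    mats = []
    for _ in range(20):
        ng = rng.integers(20, 120)
        ns = rng.integers(2, 9)
        arr = rng.integers(1, 5000, size=(ng, ns))
        mats.append(make_counts(arr))
    return mats
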