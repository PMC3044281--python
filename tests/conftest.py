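import numpy as np
import pytest

from epinull import GenotypeDataset, NullSimConfig, simulate_null_dataset


@pytest.fixture
def small_null_dataset() -> GenotypeDataset:
    """200 samples x 6 SNPs of pure noise, balanced phenotype."""
    return simulate_null_dataset(NullSimConfig(n_samples=200, n_snps=6, seed=42))


@pytest.fixture
def tiny_dataset() -> GenotypeDataset:
    """Hand-sized dataset for exact bookkeeping checks."""
    rng = np.random.default_rng(7)
    geno = rng.integers(0, 3, size=(12, 4), dtype=np.int8)
    phen = np.array([1, 0] * 6, dtype=np.int8)
    return GenotypeDataset(geno, phen, [f"rs{i}" for i in range(4)])
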