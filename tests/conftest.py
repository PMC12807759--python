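import numpy as np
import pytest

from m6akit import simulate
from m6akit.matrix import MethylationMatrix, SampleRecord


@pytest.fixture(scope="session")
def toy_genome():
    """Small deterministic genome + annotation + DRACH truth."""
    return simulate.make_toy_genome(n_chrom=2, length=20000, n_genes=10, seed=42)


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(0)
    n = rng.integers(10, 60, size=(30, 3))
    k = rng.binomial(n, 0.15)
    samples = [
        SampleRecord("s1", technique="GLORI", category="chemical"),
        SampleRecord("s2", technique="GLORI", category="chemical"),
        SampleRecord("ivt1", technique="GLORI", category="chemical", is_ivt=True),
    ]
    return MethylationMatrix([f"site{i}" for i in range(30)], samples, k, n)
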