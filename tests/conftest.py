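import numpy as np
import pandas as pd
import pytest

from hwebench.genotype_io import GenotypeMatrix, PopMap


def make_matrix(calls, samples=None, pops=None):
    """Build a GenotypeMatrix (and optional PopMap) from a raw call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = samples or [f"s{i}" for i in range(n)]
    loci = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 10,
            "ref": "A",
            "alt": "T",
        },
        index=pd.Index([f"L{j}" for j in range(m)], name="locus"),
    )
    g = GenotypeMatrix(samples, loci, calls)
    if pops is None:
        return g
    return g, PopMap(dict(zip(samples, pops)))


@pytest.fixture
def tiny_matrix():
    """4 diploids x 3 loci with one missing call."""
    return make_matrix(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, -1],
            [0, 2, 1],
        ]
    )


@pytest.fixture
def two_pop_dataset():
    """Two populations of 4, one locus fixed for opposite alleles."""
    calls = np.array(
        [
            [0, 0, 1],
            [0, 1, 1],
            [0, 0, 0],
            [0, 1, 2],
            [2, 0, 1],
            [2, 1, 0],
            [2, 0, 2],
            [2, 1, 1],
        ],
        dtype=np.int8,
    )
    return make_matrix(calls, pops=["A"] * 4 + ["B"] * 4)


def random_matrix(rng, n=20, m=30, missing_rate=0.1):
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    calls[rng.random((n, m)) < missing_rate] = -1
    return make_matrix(calls)
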