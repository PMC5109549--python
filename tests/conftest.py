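import numpy as np
import pytest

from hitgwas import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(values, ploidy_mode="outbred", chrom=None, pos=None):
    """GenotypeMatrix from a raw array with simple metadata."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return GenotypeMatrix(
        values,
        [f"ind{i}" for i in range(n)],
        [f"m{j}" for j in range(p)],
        chrom if chrom is not None else np.array(["chr1"] * p, dtype=object),
        pos if pos is not None else np.arange(1, p + 1) * 1000,
        ploidy_mode,
    )


@pytest.fixture
def two_block_genotypes(rng):
    """Six markers: two independent latent blocks of three highly
    correlated markers each (within-block |r| ~ 0.9, across ~ 0)."""
    n = 200
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    cols = [a + 0.3 * rng.normal(size=n) for _ in range(3)]
    cols += [b + 0.3 * rng.normal(size=n) for _ in range(3)]
    return make_genotypes(np.column_stack(cols))


@pytest.fixture
def random_genotypes(rng):
    vals = rng.binomial(2, 0.3, size=(60, 25)).astype(float)
    # guard against monomorphic columns
    vals[0] = 0.0
    vals[1] = 2.0
    return make_genotypes(vals)
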