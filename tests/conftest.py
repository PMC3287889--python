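import numpy as np
import pytest

from burdenscan import GenotypeMatrix


def make_genotypes(n: int, m: int, seed: int = 0, maf_low: float = 0.02, maf_high: float = 0.4) -> GenotypeMatrix:
    """Unstructured random genotype panel for unit tests."""
    rng = np.random.default_rng(seed)
    freq = rng.uniform(maf_low, maf_high, size=m)
    counts = rng.binomial(2, freq, size=(n, m)).astype(float)
    # guard against monomorphic columns so weight schemes are well defined
    for j in range(m):
        if np.ptp(counts[:, j]) == 0:
            counts[0, j] = 1.0 - counts[0, j] if counts[0, j] in (0, 1) else 1.0
    return GenotypeMatrix(
        counts=counts,
        variant_ids=[f"v{j}" for j in range(m)],
        chromosome=["chr1"] * m,
        position=np.arange(1, m + 1),
    )


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """3 individuals x 3 variants with known counts and MAFs."""
    counts = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, 1.0, 0.0],
            [2.0, 0.0, 1.0],
        ]
    )
    return GenotypeMatrix(
        counts=counts,
        variant_ids=["a", "b", "c"],
        chromosome=["chr1", "chr1", "chr2"],
        position=[100, 200, 300],
    )


@pytest.fixture
def small_panel() -> GenotypeMatrix:
    return make_genotypes(80, 10, seed=7)
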