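import numpy as np
import pytest

from demog.genotype_io import MISSING, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


def random_genotypes(rng, n_ind=8, n_sites=12, missing=0.0):
    d = rng.integers(0, 3, size=(n_ind, n_sites)).astype(np.int8)
    if missing:
        d[rng.random(d.shape) < missing] = MISSING
    return GenotypeMatrix(
        [f"ind{i}" for i in range(n_ind)],
        [f"1:{100 * (s + 1)}" for s in range(n_sites)],
        d,
    )


@pytest.fixture
def small_matrix(rng):
    return random_genotypes(rng, n_ind=8, n_sites=12, missing=0.2)
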