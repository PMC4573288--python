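import numpy as np
import pandas as pd
import pytest

from cfmeth.core import make_pool
from cfmeth.simulate import default_pool_params, make_genome, simulate_study


@pytest.fixture(scope="session")
def study():
    """The three-pool planted study at analysis scale (shared across tests).

    One 2 Mb chromosome, 200 islands, 10 planted hotspots at level 0.9,
    depths 10/10/17, fixed seed.
    """
    genome, tracks = make_genome(seed=3)
    params = default_pool_params(depths=(10.0, 10.0, 17.0))
    data = simulate_study(genome, params, seed=3, n_planted=10)
    return genome, tracks, data


@pytest.fixture
def tiny_pool():
    """Six plus-strand loci on two chromosomes with assorted coverages."""
    return make_pool(
        "tiny",
        chrom=["chr1"] * 4 + ["chr2"] * 2,
        pos=[101, 205, 309, 413, 101, 205],
        meth=[7, 0, 10, 3, 5, 0],
        unmeth=[3, 10, 0, 3, 5, 0],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
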