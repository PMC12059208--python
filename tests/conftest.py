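import numpy as np
import pytest

from divscape.marker_data import MarkerMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, populations, species="sp", loci=None, individuals=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return MarkerMatrix(
        individuals=individuals or [f"i{k}" for k in range(n)],
        loci=loci or [f"L{j}" for j in range(m)],
        values=values,
        populations=list(populations),
        species=species,
    )


@pytest.fixture
def toy_matrix():
    """2 populations x 3 individuals, 4 loci, complete data."""
    values = [
        [1, 0, 1, 0],
        [1, 1, 0, 0],
        [0, 1, 1, 0],
        [0, 0, 1, 1],
        [1, 0, 0, 1],
        [0, 0, 1, 1],
    ]
    return make_matrix(values, ["A"] * 3 + ["B"] * 3)


@pytest.fixture
def random_matrix(rng):
    """4 populations x 5 individuals, 30 loci, ~5% missing."""
    values = (rng.random((20, 30)) < 0.4).astype(float)
    miss = rng.random((20, 30)) < 0.05
    values[miss] = np.nan
    pops = [f"P{k}" for k in range(4) for _ in range(5)]
    return make_matrix(values, pops)
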