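import numpy as np
import pytest

from windowscape.io_formats import GenotypeTable, Raster


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_table(calls, loci=None, demes=None, lons=None, lats=None):
    """Build a GenotypeTable from a nested list calls[i][j] = (a, b)."""
    calls = np.asarray(calls, dtype=np.int64)
    n, n_loci = calls.shape[:2]
    if loci is None:
        loci = [f"L{j}" for j in range(n_loci)]
    if demes is None:
        demes = ["d0"] * n
    if lons is None:
        lons = np.linspace(-5.0, -1.0, n)
    if lats is None:
        lats = np.full(n, 40.0)
    return GenotypeTable([f"i{k}" for k in range(n)], list(demes),
                         np.asarray(lons, float), np.asarray(lats, float),
                         list(loci), calls)


@pytest.fixture
def toy_table():
    # 4 individuals, 2 loci; i3 missing locus L1
    return make_table([
        [(120, 120), (200, 204)],
        [(120, 124), (200, 200)],
        [(124, 124), (204, 204)],
        [(120, 124), (0, 0)],
    ])


def random_genotype_table(rng, n=20, n_loci=5, n_demes=4, missing_rate=0.05):
    alleles = np.arange(100, 112, 2)
    calls = rng.choice(alleles, size=(n, n_loci, 2))
    miss = rng.random((n, n_loci)) < missing_rate
    calls[miss] = 0
    demes = [f"d{k % n_demes}" for k in range(n)]
    lons = rng.uniform(-8, 0, n)
    lats = rng.uniform(36, 43, n)
    return make_table(calls, demes=demes, lons=lons, lats=lats)


@pytest.fixture
def random_table(rng):
    return random_genotype_table(rng)


@pytest.fixture
def small_raster():
    data = np.array([[1.0, 2.0, 3.0],
                     [4.0, np.nan, 6.0],
                     [7.0, 8.0, 9.0]])
    return Raster(data, xllcorner=-5.0, yllcorner=40.0, cellsize=0.5)


def random_distance_matrix(rng, n):
    """A genuine (Euclidean) distance matrix on random points."""
    pts = rng.random((n, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return d
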