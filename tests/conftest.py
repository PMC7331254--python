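import numpy as np
import pytest

from hicdelta.grid import GenomeGrid
from hicdelta.contacts import ContactMatrix


@pytest.fixture
def small_grid() -> GenomeGrid:
    """Two short chromosomes, 25-kb bins (10 and 6 bins)."""
    return GenomeGrid(("chrA", "chrB"), (250_000, 150_000), 25_000)


@pytest.fixture
def one_chrom_grid() -> GenomeGrid:
    """One 1-Mb chromosome at 25 kb (40 bins)."""
    return GenomeGrid(("chr1",), (1_000_000,), 25_000)


def symmetric(n: int, rng: np.random.Generator, integer: bool = False) -> np.ndarray:
    """Random symmetric non-negative matrix."""
    a = rng.random((n, n)) * 10
    if integer:
        a = np.floor(a)
    return np.triu(a) + np.triu(a, 1).T


def matrix_of(grid: GenomeGrid, fill, kind: str = "oe") -> ContactMatrix:
    """Constant-fill (or per-chrom dict) ContactMatrix on a grid."""
    data = {}
    for c in grid.chrom_names:
        n = grid.n_bins(c)
        if isinstance(fill, dict):
            data[c] = fill[c]
        else:
            data[c] = np.full((n, n), float(fill))
    return ContactMatrix(grid, data, kind)
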