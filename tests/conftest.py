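import numpy as np
import pytest

from hicarch import ContactMatrix, GenomeSpec


@pytest.fixture
def toy_genome():
    """Two chromosomes, 120 + 80 bins at 1 Mb."""
    return GenomeSpec({"chr1": 120_000_000, "chr2": 80_000_000}, 1_000_000)


@pytest.fixture
def one_chrom_100():
    return GenomeSpec({"chr1": 100_000_000}, 1_000_000)


def uniform_matrix(genome: GenomeSpec, value: int = 1) -> ContactMatrix:
    n = genome.nbins
    counts = np.full((n, n), value, dtype=np.int64)
    np.fill_diagonal(counts, 0)
    return ContactMatrix(genome, counts)


def random_matrix(genome: GenomeSpec, seed: int = 0, lam: float = 20.0) -> ContactMatrix:
    rng = np.random.default_rng(seed)
    n = genome.nbins
    counts = np.zeros((n, n), dtype=np.int64)
    iu, ju = np.triu_indices(n, k=1)
    v = rng.poisson(lam, size=iu.size)
    counts[iu, ju] = v
    counts[ju, iu] = v
    return ContactMatrix(genome, counts)
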