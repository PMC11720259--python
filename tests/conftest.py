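import numpy as np
import pytest

from rohscan.io import GenotypeMatrix, Marker


def make_gm(calls, positions=None, chromosome=1, chromosomes=None, individuals=None):
    """Build a small GenotypeMatrix from a 2-D list/array of codes.

    ``positions`` default to 10 kb spacing; ``chromosomes`` may be a
    per-SNP array for multi-chromosome fixtures.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [10_000 * (j + 1) for j in range(m)]
    if chromosomes is None:
        chromosomes = [chromosome] * m
    if individuals is None:
        individuals = [f"ind{i + 1}" for i in range(n)]
    markers = [
        Marker(f"snp{j + 1}", int(chromosomes[j]), int(positions[j]), ("A", "G"))
        for j in range(m)
    ]
    return GenotypeMatrix(individuals, markers, calls)


@pytest.fixture
def hom_run_gm():
    """One individual, 100 all-homozygous SNPs evenly spaced over ~2 Mb."""
    return make_gm(np.zeros((1, 100)), positions=[20_000 * (j + 1) for j in range(100)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
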