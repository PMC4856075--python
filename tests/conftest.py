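import numpy as np
import pytest

from srnakit import align as al
from srnakit import simulate as sim

SMALL_GENOME = sim.GenomeSpec(
    n_chromosomes=2, chrom_length=12000,
    n_mirna=8, n_pirna=8, n_trna=4, n_rrna=2, n_transposon=3, n_gene=10,
    seed=11,
)


@pytest.fixture(scope="session")
def small_genome():
    return sim.build_genome(SMALL_GENOME)


@pytest.fixture(scope="session")
def small_experiment(small_genome):
    chroms, ann = small_genome
    spec = sim.LibrarySpec(reads_per_library=2000, seed=11)
    reads, truth, barcode_map = sim.simulate_libraries(chroms, ann, spec)
    return chroms, ann, spec, reads, truth, barcode_map


@pytest.fixture(scope="session")
def genome_index(small_genome):
    chroms, _ = small_genome
    return al.GenomeIndex(chroms)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
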