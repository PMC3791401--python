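import pytest

from tboxscan.annotate import assign_nearest_gene, gene_occupancies
from tboxscan.simulate import SimConfig, simulate_genome, simulate_peaks


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=7, n_scaffolds=3, n_genes=60, target_fraction=0.5,
                     n_background_peaks=40)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_peaks(small_cfg, small_genome):
    genes, _ = small_genome
    return simulate_peaks(genes, small_cfg, label="TF_A")


@pytest.fixture(scope="session")
def small_assignments(small_genome, small_peaks):
    genes, _ = small_genome
    peaks, _ = small_peaks
    assignments, unassigned = assign_nearest_gene(peaks, genes)
    return assignments, unassigned


@pytest.fixture(scope="session")
def small_occupancies(small_genome, small_assignments):
    genes, _ = small_genome
    assignments, _ = small_assignments
    return gene_occupancies(genes, assignments)
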