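import pytest

from bobaseq.simulate import sim_genome, sim_library, sim_truth


@pytest.fixture(scope="session")
def toy_truth():
    """A small ground-truthed library reused by mapper/QC tests."""
    return sim_truth(seed=11, n_genes=40, n_barcodes=150)


@pytest.fixture(scope="session")
def toy_genome():
    return sim_genome(n_genes=30, seed=7)


@pytest.fixture(scope="session")
def midsize_library(toy_genome):
    genome, genes = toy_genome
    return sim_library(genome, genes, 500, seed=8)
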