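import pytest

from hybridshock import quant, syndata


@pytest.fixture(scope="session")
def genome_small():
    """Small diverged genome pair shared by read-assignment tests."""
    return syndata.generate_genome_pair(
        n_chrom=2, chrom_len=30_000, n_genes=60, divergence=0.2, seed=7)


@pytest.fixture(scope="session")
def concat_index_small(genome_small):
    genomes, _, _ = genome_small
    return quant.build_concat_index(genomes, k=21)


@pytest.fixture(scope="session")
def study_table():
    """Default four-way count table with the standard effect design."""
    design = syndata.make_effect_design(n_genes=300, seed=11)
    lengths = syndata.sample_allele_lengths(design, seed=12)
    table = syndata.simulate_counts(design, seed=13, allele_lengths=lengths)
    return design, table
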