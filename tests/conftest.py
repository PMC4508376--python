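import numpy as np
import pytest

import guidepool as gp


@pytest.fixture(scope="session")
def synthetic_genome():
    """A 20-gene random genome with mixed isoform structure."""
    return gp.make_genome(
        gp.GenomeSpec(n_genes=20, isoforms_per_gene=(1, 3), seed=11)
    )


@pytest.fixture(scope="session")
def genome_files(synthetic_genome, tmp_path_factory):
    d = tmp_path_factory.mktemp("genome")
    fasta = d / "genome.fasta"
    gff3 = d / "genome.gff3"
    fasta.write_text(synthetic_genome.fasta)
    gff3.write_text(synthetic_genome.gff3)
    return fasta, gff3


@pytest.fixture(scope="session")
def loaded(genome_files):
    fasta, gff3 = genome_files
    genome = gp.read_genome(fasta)
    genes = gp.read_annotation(gff3, genome)
    return genome, genes


@pytest.fixture(scope="session")
def designed(loaded):
    genome, genes = loaded
    records, bed, report = gp.design_library(genome, genes)
    return records, bed, report


@pytest.fixture(scope="session")
def library_df(designed):
    return gp.library_table(designed[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(20150620)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def layout():
    return gp.ReadLayout(anchor5="TTGTGGAAAGGACGAAACACCG", anchor3="GTTTTAGAGCTAGAAATAGCAAG")
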