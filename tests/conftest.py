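"""Shared fixtures: hand-built genes and session-scoped synthetic cohorts."""

import pytest

from mirnome.genemodel import GenomicInterval, MirnaGene
from mirnome.simulate import SimulationConfig, simulate_cohort

# single fixed seed for every session-scoped synthetic cohort
TEST_SEED = 1234


def make_gene(
    strand: str = "+",
    chrom: str = "chr1",
    start: int = 1000,
    precursor_len: int = 60,
    m5: int = 22,
    m3: int = 22,
    flank_len: int = 25,
    gene_id: str = "MI-TEST-0001",
    single_arm: str = "",
) -> MirnaGene:
    """A synthetic hairpin with arms flush with the precursor ends."""
    prec = GenomicInterval(chrom, start, start + precursor_len, strand)
    if strand == "+":
        iv5 = GenomicInterval(chrom, start, start + m5, strand)
        iv3 = GenomicInterval(chrom, start + precursor_len - m3, start + precursor_len, strand)
    else:
        iv5 = GenomicInterval(chrom, start + precursor_len - m5, start + precursor_len, strand)
        iv3 = GenomicInterval(chrom, start, start + m3, strand)
    return MirnaGene(
        gene_id=gene_id,
        name="mir-test-1",
        precursor=prec,
        mature_5p=None if single_arm == "3p" else iv5,
        mature_3p=None if single_arm == "5p" else iv3,
        flank_len=flank_len,
    )


@pytest.fixture(scope="session")
def plus_gene():
    return make_gene("+")


@pytest.fixture(scope="session")
def minus_gene():
    return make_gene("-", gene_id="MI-TEST-0002")


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort: 200 genes, 50 tumor/normal pairs."""
    return simulate_cohort(SimulationConfig(rng_seed=TEST_SEED))


@pytest.fixture(scope="session")
def swapped_cohort():
    """Smaller cohort with two planted tumor/normal sample swaps."""
    return simulate_cohort(
        SimulationConfig(rng_seed=TEST_SEED, n_genes=50, n_sample_pairs=20, n_swapped_pairs=2)
    )
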