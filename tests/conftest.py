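import numpy as np
import pytest

from poolqtl.synthetic_data import GenomeModel, QtlModel


@pytest.fixture
def small_genome() -> GenomeModel:
    """Two 2-Mbp chromosomes, 20 SNPs each, suppressed block on chr1."""
    return GenomeModel.regular(
        n_chrom=2,
        chrom_length=2_000_000,
        snps_per_chrom=20,
        block=("chr1", 1, 800_000),
    )


@pytest.fixture
def small_qtl(small_genome) -> QtlModel:
    return QtlModel(
        locus=("chr1", small_genome.nearest_snp("chr1", 500_000)),
        effect=250.0,
        donor_dosage_fraction=0.25,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
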