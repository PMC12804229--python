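import numpy as np
import pandas as pd
import pytest

from pathgwas import GenotypeMatrix, SimConfig, simulate_genotypes


def make_genotypes(dosages, chrom=None, pos=None) -> GenotypeMatrix:
    """Tiny genotype matrix from a literal dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    chrom = chrom if chrom is not None else [1] * m
    pos = pos if pos is not None else [100 * (j + 1) for j in range(m)]
    snps = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "a1": "A",
            "a2": "G",
        }
    )
    samples = [f"i{i}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(dosages=dosages, snps=snps, samples=samples)


@pytest.fixture(scope="session")
def family_panel() -> GenotypeMatrix:
    """150 individuals (25 sib pairs), 2 chromosomes, mild missingness."""
    config = SimConfig(
        n_individuals=150,
        n_chromosomes=2,
        blocks_per_chrom=4,
        snps_per_block=15,
        within_block_ld=0.4,
        missing_rate=0.02,
        n_sib_pairs=25,
        seed=11,
    )
    return simulate_genotypes(config)


@pytest.fixture(scope="session")
def clean_panel() -> GenotypeMatrix:
    """200 unrelated individuals, 3 chromosomes, no missingness."""
    config = SimConfig(
        n_individuals=200,
        n_chromosomes=3,
        blocks_per_chrom=5,
        snps_per_block=10,
        maf_range=(0.15, 0.5),
        within_block_ld=0.3,
        missing_rate=0.0,
        seed=23,
    )
    return simulate_genotypes(config)
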