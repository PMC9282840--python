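import numpy as np
import pandas as pd
import pytest

from longprs import simulate
from longprs.target import GenotypeData


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted-signal cohort shared by read-only tests."""
    geno, pheno, ss, arch = simulate.tradeoff_cohort(
        n_individuals=600, seed=11, n_null=20,
        strong_bands=((6.0, 30),), weak_bands=((3.0, 30),))
    return geno, pheno, ss, arch


@pytest.fixture()
def toy_geno():
    """Hand-sized genotype container: 6 individuals x 4 SNPs, one missing."""
    matrix = np.array([
        [0, 1, 2, 0],
        [1, 1, 0, 1],
        [2, 0, 1, 2],
        [0, 2, 2, 0],
        [1, 0, 0, np.nan],
        [2, 2, 1, 1],
    ], dtype=float)
    variants = pd.DataFrame({
        "snp_id": ["rsA", "rsB", "rsC", "rsD"],
        "chrom": ["1", "1", "1", "2"],
        "pos": [1000, 2000, 600_000, 1000],
        "counted_allele": ["A", "C", "G", "T"],
        "other_allele": ["G", "T", "A", "C"],
        "maf": [0.4, 0.4, 0.4, 0.3],
    })
    samples = np.array([f"i{k}" for k in range(6)])
    return GenotypeData(samples=samples, variants=variants, matrix=matrix)
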