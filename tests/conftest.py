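import numpy as np
import pandas as pd
import pytest

from prspipe.io_genotype import GenotypeMatrix, SummaryStats
from prspipe.simulate import SimConfig, simulate_cohort


def make_genotypes(dosage, chrom=None, pos=None, a1="A", a2="G", snp_ids=None):
    """Build a GenotypeMatrix from a raw dosage array with default metadata."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variants = pd.DataFrame(
        {
            "snp_id": snp_ids or [f"snp{j}" for j in range(m)],
            "chrom": chrom or ["1"] * m,
            "pos": pos or [1000 * (j + 1) for j in range(m)],
            "a1": [a1] * m if isinstance(a1, str) else a1,
            "a2": [a2] * m if isinstance(a2, str) else a2,
        }
    )
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosage)


def make_sumstats(snp_ids, beta, pvalue, chrom=None, pos=None, ea="A", oa="G"):
    m = len(snp_ids)
    return SummaryStats(
        pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": chrom or ["1"] * m,
                "pos": pos or [1000 * (j + 1) for j in range(m)],
                "effect_allele": [ea] * m if isinstance(ea, str) else ea,
                "other_allele": [oa] * m if isinstance(oa, str) else oa,
                "beta": beta,
                "pvalue": pvalue,
            }
        )
    )


@pytest.fixture(scope="session")
def cohort():
    """One default-condition synthetic study shared across tests."""
    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
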