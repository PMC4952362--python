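import numpy as np
import pandas as pd
import pytest

from cytoqtl.containers import GenotypeMatrix
from cytoqtl.synthdata import SimScenario, simulate_covariates, simulate_genotypes


def make_genotypes(dosages: np.ndarray, chrom: str = "chr1", spacing: int = 1000) -> GenotypeMatrix:
    """GenotypeMatrix from a raw samples x SNPs dosage array."""
    n, m = dosages.shape
    snp_ids = [f"rs{i:04d}" for i in range(m)]
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * spacing,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    return GenotypeMatrix(
        dosages=pd.DataFrame(dosages.astype(float), index=samples, columns=snp_ids),
        snps=snps,
    )


@pytest.fixture(scope="session")
def small_scenario() -> SimScenario:
    return SimScenario(n_samples=120, n_genes=6, snps_per_gene_region=6, ld_rho=0.6)


@pytest.fixture(scope="session")
def small_genotypes(small_scenario):
    return simulate_genotypes(small_scenario, seed=42)


@pytest.fixture(scope="session")
def small_covariates(small_scenario):
    return simulate_covariates(small_scenario.n_samples, seed=43)
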