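import numpy as np
import pytest

from crosstwas.config import SimulationConfig
from crosstwas.simulate import build_ld_reference, simulate_study


@pytest.fixture(scope="session")
def base_study():
    """Moderate study reused across oracle tests: 25 genes, 2 tissues,
    expression-mediated phenotype, no direct SNP effects."""
    cfg = SimulationConfig(
        n_ref=400, n_gwas=5000, n_train=100, n_test=100,
        n_genes=25, snps_per_gene=8, n_tissues=2, ld_rho=0.5,
        mediated_h2=0.15, direct_h2=0.0, seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def insample_ld(base_study):
    """LD estimated in the GWAS cohort itself, for equivalence oracles."""
    return build_ld_reference(base_study.gwas_cohort.genotypes, base_study.annotation)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
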