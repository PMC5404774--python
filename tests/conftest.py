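import numpy as np
import pytest

from snpconsensus import GenotypeTable, PhenotypeVector, SimulationSpec
from snpconsensus.simulate import simulate_with_effects


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_csv(tmp_path):
    """4 samples x 3 SNPs with one phenotype column and a sample-id column."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "sample,PA,snp1,snp2,snp3\n"
        "a,0.5,1,2,3\n"
        "b,-0.1,1,1,2\n"
        "c,1.2,2,1,1\n"
        "d,0.0,3,2,1\n"
    )
    return path


@pytest.fixture
def small_genotypes():
    return GenotypeTable(
        sample_ids=["a", "b", "c", "d"],
        snp_ids=["s1", "s2", "s3"],
        codes=np.array([[1, 2, 3], [1, 1, 2], [2, 1, 1], [3, 2, 1]]),
    )


@pytest.fixture(scope="session")
def planted_small():
    """Planted-signal dataset small enough for fast forest fits."""
    spec = SimulationSpec(n=300, p=40, causal_snps={7: 0.8}, noise_sd=0.35,
                          seed=77)
    genotypes, phenotype, truth = simulate_with_effects(spec)
    return genotypes, phenotype, truth
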