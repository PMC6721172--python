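import numpy as np
import pandas as pd
import pytest

from fenet.pheno import qc_genotypes
from fenet.simdata import (
    GenotypeMatrix,
    SimConfig,
    simulate_phenotypes,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_individuals=120, n_families=5, n_snps=800, n_chromosomes=6,
        n_genes_expressed=300, seed=11,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def small_phenotypes(small_population, small_config):
    return simulate_phenotypes(
        small_population.genotypes, small_population.pedigree, small_config
    )


@pytest.fixture(scope="session")
def qc_genotypes_small(small_population):
    G, _ = qc_genotypes(small_population.genotypes)
    return G


def make_genotypes(codes: np.ndarray, chrom: str = "1",
                   positions: list[int] | None = None) -> GenotypeMatrix:
    """Hand-built genotype matrix for toy tests."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    meta = pd.DataFrame({
        "snp": [f"s{k}" for k in range(m)],
        "chrom": [chrom] * m,
        "pos": positions or list(range(1000, 1000 + 1000 * m, 1000)),
        "a1": ["A"] * m,
        "a2": ["B"] * m,
    })
    G = GenotypeMatrix(codes, [f"i{j}" for j in range(n)], meta)
    meta["maf"] = G.maf()
    return G
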