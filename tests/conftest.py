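import numpy as np
import pytest

from sexchrom import simcross


@pytest.fixture(scope="session")
def small_config() -> simcross.SimConfig:
    """Desk-scale cross: 10 genes x 100 codons, genomic F1 plus a few RNA F2."""
    return simcross.SimConfig(
        seed=7,
        codons_per_gene=100,
        n_genes_per_region={"Xpr": 10},
        cross=simcross.CrossConfig(
            n_f1_genomic=6, n_f2_transcriptomic=6, coverage_genomic=20.0,
            coverage_rna=20.0, read_length=50, error_rate=0.001,
        ),
    )


@pytest.fixture(scope="session")
def small_genes(small_config):
    return simcross.simulate_gametolog_triplets(
        small_config, "Xpr", small_config.rng(), n_genes=10
    )


@pytest.fixture(scope="session")
def small_cross(small_config, small_genes):
    rng = np.random.default_rng(small_config.seed + 1)
    return simcross.simulate_cross(small_config, small_genes, rng)
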