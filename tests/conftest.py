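import pytest

from clonelineage.simulate import SimConfig, simulate_lineage


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast, small lineage: depth-4 tree, 3 biopsies x 5 clones."""
    return SimConfig(
        n_divisions_tracked=4,
        muts_per_division=15.0,
        n_biopsies=3,
        clones_per_biopsy=5,
        redundancy=2.0,
        culture_mut_rate=5.0,
        genome_size=100_000,
        mito_sites=20,
        n_germline_sites=10,
        n_nonclonal=1,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_lineage(small_config)
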