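import pytest

from sexmarker import SimulationConfig, simulate_genotypes
from sexmarker.fixtures import load_fixture_table5


@pytest.fixture(scope="session")
def table5():
    """The four-species ten-marker genotype matrices."""
    return load_fixture_table5()


@pytest.fixture()
def clean_sim():
    """Small noise-free ZW simulation with its truth classes."""
    config = SimulationConfig(
        n_female=10,
        n_male=10,
        n_autosomal=100,
        n_sexlinked=10,
        genotyping_error_rate=0.0,
        missing_rate=0.0,
        seed=11,
    )
    return simulate_genotypes(config)
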