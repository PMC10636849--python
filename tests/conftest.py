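import pytest

from skincat.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale scenario used by most integration-style tests."""
    return ScenarioConfig(
        n_families=12,
        n_species=8,
        n_transmission_species=3,
        n_genes=200,
        genome_length=20_000,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config)
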