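import pytest

from taxonlink.synthetic import WorldConfig, generate_world, paper_fixture_world


@pytest.fixture(scope="session")
def clean_world():
    """A 50-species world with no planted pathologies."""
    return generate_world(WorldConfig(n_species=50, seed=11))


@pytest.fixture(scope="session")
def planted_world():
    """A 200-species world with every pathology planted at 5%."""
    return generate_world(
        WorldConfig(
            n_species=200,
            seed=23,
            rate_homonym=0.05,
            rate_hemihomonym=0.05,
            rate_synonym_pair=0.05,
            rate_missing_author=0.05,
            rate_misspelling=0.05,
            rate_stale_gbif_link=0.05,
            rate_merged_ncbi=0.05,
            rate_chresonym=0.05,
        )
    )


@pytest.fixture(scope="session")
def fixture_world():
    """The fixed world encoding the documented curation cases."""
    return paper_fixture_world()
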