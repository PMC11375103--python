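import pytest

from beemito import default_catalog, generate_population, study_spec


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def units(catalog):
    return catalog.units


@pytest.fixture(scope="session")
def study_population(catalog):
    """The 1143-bee study-replica population (shared; treat as read-only)."""
    return generate_population(study_spec(seed=11), catalog)
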