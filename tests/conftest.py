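import pytest

from agrodelim.karyotype import build_default_two_species_model


@pytest.fixture(scope="session")
def default_model():
    """Species-wide two-taxon model with both polymorphisms segregating."""
    return build_default_two_species_model(0.5, 0.5)


@pytest.fixture(scope="session")
def albanian_model():
    """Study-population model: orphicus fixed at n=42, lurae polymorphic."""
    return build_default_two_species_model(0.0, 0.5)
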