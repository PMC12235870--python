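import pytest

from cside.genome_model import default_allele_models, default_regions
from cside.synthetic_data import (
    fixture_primer_pairs,
    make_allele_templates,
    study_allele_models,
)


@pytest.fixture(scope="session")
def models():
    return default_allele_models()


@pytest.fixture(scope="session")
def regions():
    return default_regions()


@pytest.fixture(scope="session")
def study():
    """(models, regions) with 150-window (1.5 Mbp) scored regions."""
    return study_allele_models()


@pytest.fixture(scope="session")
def templates():
    return make_allele_templates(seed=0)


@pytest.fixture(scope="session")
def primer_pairs():
    return fixture_primer_pairs()
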