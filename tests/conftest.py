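import pytest

from neuropepminer.catalog import load_catalog
from neuropepminer.synthetic import generate_transcriptome


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def catalog_by_family(catalog):
    return {e.family_name: e for e in catalog}


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic transcriptome shared by search/pipeline tests."""
    return generate_transcriptome(n_precursors=6, n_decoys=6, seed=11)
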