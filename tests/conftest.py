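import pytest

from p73kit import gene_model, synthetic_data


@pytest.fixture(scope="session")
def toy_model():
    return synthetic_data.toy_exon_model()


@pytest.fixture(scope="session")
def dm(toy_model):
    return gene_model.derive_diagnostic_junctions(toy_model, gene_model.DEFAULT_CLASS_SPEC)
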