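import pytest

from faerspv.synthetic_faers import SignalPair, SyntheticConfig, generate_bundle
from faerspv.vocab import VocabularyBundle


@pytest.fixture(scope="session")
def small_config():
    """A small bundle with one strong injected signal, duplicates and
    deletions, used by most integration tests."""
    return SyntheticConfig(
        n_cases=4000, seed=42,
        signal_pairs=[SignalPair("MONTELUKAST", "Anxiety", 8.0)],
        duplicate_rate=0.10, deletion_rate=0.02,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(small_config, out)


@pytest.fixture(scope="session")
def small_vocab(small_bundle):
    return VocabularyBundle.read(small_bundle.paths["drug_dict"],
                                 small_bundle.paths["meddra"])
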