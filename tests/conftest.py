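import pytest

from fp2mol.fixtures import FixtureSpec, make_fixture
from fp2mol.tokenizer import TokenVocabulary


@pytest.fixture(scope="session")
def fixture_set():
    """Small synthetic fixture bundle shared across the suite."""
    return make_fixture(FixtureSpec(n_molecules=60, fp_len=64, seed=11,
                                    n_folds=4))


@pytest.fixture(scope="session")
def corpus(fixture_set):
    return fixture_set.corpus


@pytest.fixture(scope="session")
def vocab(corpus):
    return TokenVocabulary.from_corpus(
        [m.smiles_canonical for m in corpus], min_count=0)


@pytest.fixture(scope="session")
def tiny_vocab():
    """Hand-built vocabulary for constructing exact token sequences."""
    return TokenVocabulary(tokens=("$", "*", "&", "C", "O", "N", "(", ")",
                                   "=", "1", "c", "[nH]", "R", "L"))
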