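import pytest

from healthlit import Document, load_lexicon, load_ruleset


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def ruleset():
    return load_ruleset()


@pytest.fixture
def make_doc():
    def _make(text: str, **kwargs) -> Document:
        return Document.from_text(text, **kwargs)

    return _make
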