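import pytest

from ademiner import Document, default_gazetteers, default_lexicons


@pytest.fixture(scope="session")
def gazetteers():
    return default_gazetteers()


@pytest.fixture(scope="session")
def dystonia_lexicons():
    return default_lexicons(["dystonia"])


@pytest.fixture(scope="session")
def epse_lexicons():
    return default_lexicons(["dystonia", "akathisia", "parkinsonism", "tardive_dyskinesia"])


def make_doc(text: str, doc_id: str = "d0", patient_id: str | None = "p0") -> Document:
    return Document(doc_id=doc_id, text=text, patient_id=patient_id)
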