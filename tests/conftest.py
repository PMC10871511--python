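import pytest

from eifrag.engine import enumerate_fragments
from eifrag.mechanisms import builtin_catalogue


@pytest.fixture(scope="session")
def catalogue():
    return builtin_catalogue()


@pytest.fixture(scope="session")
def qfa_predictions(catalogue):
    return enumerate_fragments("QFA", catalogue)


@pytest.fixture(scope="session")
def cia_predictions(catalogue):
    return enumerate_fragments("CIA", catalogue)
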