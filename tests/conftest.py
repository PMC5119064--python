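import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

from lirscan import (
    builtin_motif,
    load_background,
    load_lir_motifs,
    load_lir_pssm,
)


@pytest.fixture(scope="session")
def bg():
    return load_background()


@pytest.fixture(scope="session")
def records():
    return load_lir_motifs()


@pytest.fixture(scope="session")
def xlir():
    return builtin_motif("xlir")


@pytest.fixture(scope="session")
def clir():
    return builtin_motif("clir")


@pytest.fixture(scope="session")
def ref_pssm():
    return load_lir_pssm()
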