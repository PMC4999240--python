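import pytest

from noncommnet.cli_io import fixture_generator
from noncommnet.models import RatchetSpec, SeqSpec


@pytest.fixture(scope="session")
def ratchet22():
    return RatchetSpec(2, 2, 1, 1, 1)


@pytest.fixture(scope="session")
def seq4_reduced():
    return SeqSpec(4, reduced=True)


@pytest.fixture(scope="session")
def seq3_full():
    return SeqSpec(3, reduced=False)


@pytest.fixture(scope="session")
def ratchet_suites():
    return fixture_generator("ratchet", seed=20240917)


@pytest.fixture(scope="session")
def seq_suites():
    return fixture_generator("sequestration", seed=20240917)
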