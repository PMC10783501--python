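import pytest
from hypothesis import settings

from topobind import Conditions, DNASubstrate, get_preset

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sytox():
    return get_preset("SYTOX_Orange")


@pytest.fixture(scope="session")
def etbr():
    return get_preset("EtBr")


@pytest.fixture(scope="session")
def sybr_gold():
    return get_preset("SYBR_Gold")


@pytest.fixture(scope="session")
def tmp_dye():
    return get_preset("TMP")


@pytest.fixture(scope="session")
def dna_42kb():
    """The 42 kb single-molecule construct (closed, initially relaxed)."""
    return DNASubstrate(N_bp=42000, C=100.0)


@pytest.fixture(scope="session")
def pbr322():
    """pBR322 plasmid at sigma0 = -5%."""
    return DNASubstrate.from_sigma0(N_bp=4361, sigma0=-0.05, C=50.0)


@pytest.fixture(scope="session")
def sm_conditions():
    """Single-molecule solution conditions: dilute DNA, 24 C, no force."""
    return Conditions(c_total=250e-9, c_dna_bp=10e-12)
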