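import pytest

from psira import build_index, encode_reference
from psira.fixtures import generate_genome

FIG1_SEQ = "AGGTCGATTCGGGACC"
LMP_REF = "TTAGGTCGATTCATTT"  # contains AGGTCGATTC but not AGGTCGATTCG
LMP_PATTERN = "AGGTCGATTCGGGACC"


@pytest.fixture(scope="session")
def fig1_genome():
    return encode_reference([("x", FIG1_SEQ)])


@pytest.fixture(scope="session")
def fig1_index(fig1_genome):
    return build_index(fig1_genome, 4, 1)


@pytest.fixture(scope="session")
def lmp_index():
    return build_index(encode_reference([("r", LMP_REF)]), 1, 2)


@pytest.fixture(scope="session")
def genome_1k():
    return generate_genome(1000, seed=42)
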