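import pytest

from aademand import load_pack, solve_table


@pytest.fixture(scope="session")
def pack():
    return load_pack()


@pytest.fixture(scope="session")
def result(pack):
    return solve_table(pack.components, pack.constants)
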