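import pytest

from epitoolkit.datasets import load_table1
from epitoolkit.io_formats import read_newick


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def ladder8():
    """8-leaf ladder tree used across loss-inference tests."""
    return read_newick("(((((((A,B),C),D),E),F),G),H);")
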