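import numpy as np
import pytest

from phylocare import parse_newick
from phylocare.simulate import make_dendrobatid_like_fixture, simulate_yule_tree


@pytest.fixture(scope="session")
def tree3():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree4():
    return parse_newick("((A:0.3,B:0.7):0.5,(C:1.1,D:0.2):0.4);")


@pytest.fixture(scope="session")
def tree5():
    return parse_newick("(((A:0.2,B:0.6):0.3,C:0.9):0.4,(D:0.5,E:1.1):0.7);")


@pytest.fixture(scope="session")
def yule100():
    return simulate_yule_tree(100, seed=41, height=1.0)


@pytest.fixture(scope="session")
def yule200():
    return simulate_yule_tree(200, seed=42, height=1.0)


@pytest.fixture(scope="session")
def dendro_fixture():
    """The 220-species dendrobatid-like dataset (shared across tests)."""
    table, tree, truth = make_dendrobatid_like_fixture(seed=1)
    return table, tree, truth
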