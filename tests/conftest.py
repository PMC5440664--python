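import numpy as np
import pytest

from phaseuncouple import synthetic_data as syn
from phaseuncouple.phylo_io import Phylogeny


@pytest.fixture(scope="session")
def toy_tree():
    """((A:1,B:1):1,C:2); root age 2."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree20():
    return syn.simulate_tree(20, birth=1.0, seed=101)


@pytest.fixture(scope="session")
def tree64():
    return syn.simulate_tree(64, birth=1.0, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
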