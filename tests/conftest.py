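import numpy as np
import pytest

from c4evo.tree import flaveria_tree, number_nodes, parse_newick


@pytest.fixture(scope="session")
def ftree():
    """The packaged 16-species Flaveria tree with unit branch lengths."""
    return flaveria_tree()


@pytest.fixture(scope="session")
def overrides(ftree):
    return ftree.preceding_overrides()


@pytest.fixture
def cherry():
    return number_nodes(parse_newick("(A:1,B:1);"))


@pytest.fixture
def quartet():
    return number_nodes(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


C3_SPECIES = ["F_robusta", "F_cronquistii"]
C4_SPECIES = ["F_kochiana", "F_bidentis", "F_trinervia", "F_australasica"]


@pytest.fixture(scope="session")
def c3_ids():
    return list(C3_SPECIES)


@pytest.fixture(scope="session")
def c4_ids():
    return list(C4_SPECIES)
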