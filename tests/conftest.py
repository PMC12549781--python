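import itertools

import pytest

from qdnet.displayed import PhyloTree
from qdnet.generate import enumerate_small_bloblets, figure_fixtures
from qdnet.network import parse_enewick


@pytest.fixture(scope="session")
def fx():
    return figure_fixtures()


@pytest.fixture(scope="session")
def cat5():
    """All 3-cycle-free 5-leaf galled planar bloblets, up to relabeling."""
    return enumerate_small_bloblets(5, three_cycle_free=True)


@pytest.fixture(scope="session")
def cat6():
    """All 3-cycle-free 6-leaf galled planar bloblets, up to relabeling."""
    return enumerate_small_bloblets(6, three_cycle_free=True)


def tree_from_newick(text: str) -> PhyloTree:
    """Build an unrooted tree from (binary, rooted) Newick text."""
    net = parse_enewick(text)
    assert not net.hybrid_nodes()
    return PhyloTree.adopt(net)


def random_tree(n: int, seed: int) -> PhyloTree:
    import random

    from qdnet.generate import _random_binary_tree

    g = _random_binary_tree([f"x{i+1}" for i in range(n)], random.Random(seed))
    return PhyloTree.adopt(g)


def pairs(taxa):
    return itertools.combinations(sorted(taxa), 2)
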