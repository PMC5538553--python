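import numpy as np
import pytest

from crstool.phylo_models import PhyloTree, jukes_cantor
from crstool.pscore import ScoreModels
from crstool.synth_fixtures import random_hairpin_structure

EIGHT_LEAF_NEWICK = (
    "((((A:0.15,B:0.15):0.1,(C:0.15,D:0.15):0.1):0.1,"
    "(E:0.2,F:0.2):0.1):0.05,(G:0.25,H:0.25):0.05);"
)


@pytest.fixture(scope="session")
def tree3() -> PhyloTree:
    return PhyloTree.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")


@pytest.fixture(scope="session")
def tree8() -> PhyloTree:
    return PhyloTree.from_newick(EIGHT_LEAF_NEWICK)


@pytest.fixture(scope="session")
def jc():
    return jukes_cantor()


@pytest.fixture(scope="session")
def default_models() -> ScoreModels:
    return ScoreModels.default()


@pytest.fixture(scope="session")
def hairpin60():
    return random_hairpin_structure(60, 12)


def random_tree_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random binary topology over n_leaves with branch lengths in [0.05, 1]."""
    names = [f"L{i}" for i in range(n_leaves)]
    nodes = list(names)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        bl_a, bl_b = rng.uniform(0.05, 1.0, size=2)
        merged = f"({a}:{bl_a:.4f},{b}:{bl_b:.4f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def random_gtr(rng: np.random.Generator):
    from crstool.phylo_models import build_gtr

    pi = rng.dirichlet(np.full(4, 5.0))
    exch = rng.uniform(0.3, 3.0, size=6)
    return build_gtr(pi, exch)
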