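import numpy as np
import pytest

from asexpop import Genealogy


@pytest.fixture
def rng():
    return np.random.default_rng(20110303)


@pytest.fixture
def two_tip_mixed():
    """Two tips joined at time 10; branch A asexual for 4 gens, B for 0."""
    g = Genealogy()
    g.add_node("A", 0)
    g.add_node("B", 0)
    g.add_node("r", 10, is_sexual=True)
    g.add_branch("r", "A", asexual_gens=4)
    g.add_branch("r", "B", asexual_gens=0)
    g.samples = ["A", "B"]
    return g


@pytest.fixture
def four_tip_tree():
    """((A,B),(C,D)) with internal nodes at 5 and root at 10, all asexual."""
    g = Genealogy()
    for t in "ABCD":
        g.add_node(t, 0)
    g.add_node("u", 5)
    g.add_node("v", 5)
    g.add_node("r", 10, is_sexual=True)
    g.add_branch("u", "A", 5)
    g.add_branch("u", "B", 5)
    g.add_branch("v", "C", 5)
    g.add_branch("v", "D", 5)
    g.add_branch("r", "u", 5)
    g.add_branch("r", "v", 5)
    g.samples = list("ABCD")
    return g
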