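import numpy as np
import pytest

from ancstate.coding import StateSpace, State, TipStateMap, TransitionConstraintMask, CodingScheme, builtin_scheme
from ancstate.phylo import Phylogeny


@pytest.fixture
def rng():
    return np.random.default_rng(20210711)


@pytest.fixture
def balanced4():
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def five_tip():
    return Phylogeny.from_newick("((A:0.3,B:0.7):0.4,(C:0.2,(D:0.5,E:0.1):0.3):0.6);")


@pytest.fixture
def traditional5(five_tip):
    """Traditional 4-state scheme with codings for the five-tip tree (one polymorphic)."""
    scheme = builtin_scheme("traditional")
    for lab, sym in zip("ABCDE", ["0", "2", "3", "24", "4"]):
        scheme.tips.set_states(lab, sym)
    return scheme


def binary_scheme(tip_states, one_way=False):
    """k=2 scheme ('A'/'B' states); one_way=True leaves only A->B allowed."""
    space = StateSpace([State("stateA", "A", "0"), State("stateB", "B", "1")])
    if one_way:
        mask = TransitionConstraintMask.from_rules(space, [("B", "A")])
    else:
        mask = TransitionConstraintMask.full(space)
    tips = TipStateMap(space, tip_states)
    return CodingScheme("binary", space, tips, mask)


@pytest.fixture
def two_tip_binary():
    """2-tip tree with a one-way binary character: a single free rate."""
    tree = Phylogeny.from_newick("(X:1,Y:1);")
    scheme = binary_scheme({"X": "0", "Y": "1"}, one_way=True)
    return tree, scheme


def random_constrained_scheme(rng, k, n_tips, absorbing=False, polymorphic=True):
    """Random state space + mask + tip codings for oracle sweeps."""
    from ancstate.simulate import random_scheme

    return random_scheme(rng, k, n_tips, absorbing=absorbing, polymorphic=polymorphic)
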