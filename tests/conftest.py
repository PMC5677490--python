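import numpy as np
import pytest

from mustelimb import models, synth
from mustelimb.phylo import parse_newick


@pytest.fixture
def cherry():
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def quartet():
    return parse_newick("((A:1,B:1):1,(C:0.5,D:0.5):1.5);")


@pytest.fixture(scope="session")
def tree40():
    """The standard 40-tip, height-16 My study fixture."""
    return synth.make_tree(40, 16.0, seed=1)


@pytest.fixture(scope="session")
def scenario_a():
    """One scenario-A dataset (clade-level optimum shift), fixed seed."""
    scn = synth.SynthScenario(scenario="A", seed=11)
    specimens, tree, habits, truth = synth.simulate_dataset(scn)
    return scn, specimens, tree, habits, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
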