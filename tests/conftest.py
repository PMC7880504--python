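import numpy as np
import pytest

from relclock.treeio import parse_newick
from relclock.clock import BranchRates, ClockModel, REAL
from relclock.model import PhyloState, SubstModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def three_taxon_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_taxon_state():
    """Balanced 4-taxon state with unit-ish rates, handy for operator tests."""
    tree = parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
    rates = BranchRates(np.array([1.0, 0.8, 1.2, 0.9, 1.1, 0.7]), REAL)
    return PhyloState(tree, rates, ClockModel(0.6), SubstModel.default(), 2.0)


@pytest.fixture(scope="session")
def ner_census():
    """Full constraint-subset census (symbolic solve, cached for the session)."""
    from relclock.ner import classify_all_solutions
    return classify_all_solutions()


def random_yule_state(N, rng, mode=REAL, sigma=0.5):
    from relclock.synthetic import simulate_yule_tree, simulate_branch_rates
    tree = simulate_yule_tree(N, 5.0, rng)
    k = tree.n_nodes - 1
    if mode == REAL:
        values = simulate_branch_rates(k, sigma, rng)
    elif mode == "cat":
        values = rng.integers(k, size=k)
    else:
        values = rng.uniform(size=k)
    return PhyloState(tree, BranchRates(values, mode), ClockModel(sigma),
                      SubstModel.default(), 5.0)
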