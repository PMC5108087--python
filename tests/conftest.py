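import numpy as np
import pytest

from analogcrn.crn import CRN


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def decay_crn():
    """x_p -> 0 at rate k: closed-form exponential decay."""
    crn = CRN()
    crn.add_species("x_p", 1.0, rail="plus", partner="x_m")
    crn.add_species("x_m", 0.0, rail="minus", partner="x_p")
    crn.add_reaction(("x_p",), (), 0.7, "decay")
    return crn


def random_crn(rng, n_species=4, n_reactions=6):
    """A random small mass-action network for property tests."""
    crn = CRN()
    names = [f"s{i}" for i in range(n_species)]
    for name in names:
        crn.add_species(name, float(rng.uniform(0.1, 2.0)))
    for j in range(n_reactions):
        order = int(rng.integers(1, 3))
        reactants = tuple(rng.choice(names, size=order))
        products = tuple(rng.choice(names, size=int(rng.integers(0, 3))))
        crn.add_reaction(reactants, products, float(rng.uniform(0.1, 5.0)),
                         f"r{j}")
    return crn
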