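import numpy as np
import pytest

from cpcompare.structure import Atom, Chain, Residue, Structure
from cpcompare.synthetic import make_chain


@pytest.fixture
def helix_chain() -> Chain:
    return make_chain(10, "helix", chain_id="A")


@pytest.fixture
def numbered_chain_281() -> Chain:
    """A chain numbered 1..281, CA-only (the alpha-subunit span)."""
    return make_chain(281, "random-walk", seed=7, chain_id="A")


def build_chain(numbers, chain_id="A", b=20.0, name="ALA"):
    """Minimal CA-only chain over explicit author numbers."""
    residues = [
        Residue(number=n, name=name,
                atoms=[Atom(name="CA", element="C",
                            position=np.array([3.8 * i, float(i % 2), 0.0]),
                            b_factor=b)])
        for i, n in enumerate(numbers)
    ]
    return Chain(id=chain_id, residues=residues)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
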