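import numpy as np
import pytest

from netherit.genotype import NetworkChromosome


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def star_network():
    """Nine genes: root regulates eight terminals, four on and four off.

    Root is on; four activator edges switch their targets on, four repressor
    edges switch theirs off — eight terminal genes of which four are on.
    """
    heads = np.zeros(8, dtype=np.int64)
    functions = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.int8)
    return NetworkChromosome(heads, functions, root_state=1)


@pytest.fixture
def chain_network():
    """A 6-gene chain of activators with the root on: every state is 1."""
    heads = np.arange(5, dtype=np.int64)  # 0->1->2->3->4->5
    functions = np.ones(5, dtype=np.int8)
    return NetworkChromosome(heads, functions, root_state=1)
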