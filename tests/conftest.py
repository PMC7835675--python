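import numpy as np
import pytest

from ploidmeth.heterosis import CrossDesign
from ploidmeth.simulate import SimulationConfig, simulate_promoter


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def design():
    """Triploid cross: tetraploid parent weight 2/3, diploid parent 1/3."""
    return CrossDesign.triploid("A-3", "LQ1-4x", "GC-1")


@pytest.fixture(scope="session")
def default_promoter():
    """One default simulated promoter with its truth bundle (expensive-ish)."""
    cfg = SimulationConfig(seed=11)
    return simulate_promoter(cfg)


def random_dna(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
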