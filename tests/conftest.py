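import numpy as np
import pytest

from igdiv import synth


@pytest.fixture(scope="session")
def locus300():
    return synth.make_locus(300, 0.5, seed=7)


@pytest.fixture(scope="session")
def donors25(locus300):
    return synth.make_donor_set(locus300, n_donors=25, divergence=0.05, seed=8)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
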