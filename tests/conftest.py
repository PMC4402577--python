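import numpy as np
import pytest

from guidealign.pairwise import AlignParams
from guidealign.seqio import AMINO_ACIDS, Sequence


@pytest.fixture(scope="session")
def params():
    return AlignParams()


@pytest.fixture(scope="session")
def params_local():
    return AlignParams(mode="local")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_sequence(rng, length, rid="s", alphabet=AMINO_ACIDS):
    res = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
    return Sequence(rid, res)


@pytest.fixture
def make_sequences():
    def _make(n, length, seed=0, alphabet=AMINO_ACIDS):
        rng = np.random.default_rng(seed)
        return [
            random_sequence(rng, length, rid=f"s{i}", alphabet=alphabet)
            for i in range(n)
        ]

    return _make
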