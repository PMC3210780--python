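import numpy as np
import pytest

from estkit import Seq

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def make_seq():
    def _make(residues: str, sid: str = "s") -> Seq:
        return Seq(sid, residues)

    return _make
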