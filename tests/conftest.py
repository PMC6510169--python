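import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chanpred.seqio import ALPHABET, ProteinSequence

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, length: int, ident: str = "s") -> ProteinSequence:
    letters = rng.choice(list(ALPHABET), size=length)
    return ProteinSequence(id=ident, residues="".join(letters))


@pytest.fixture
def random_proteins(rng):
    def make(n: int, min_len: int = 10, max_len: int = 80):
        return [
            random_protein(rng, int(rng.integers(min_len, max_len + 1)), f"s{i}")
            for i in range(n)
        ]

    return make
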