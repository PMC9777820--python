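import numpy as np
import pytest

from mirsite.encoding import MiRNASeq, TargetSeq, standardize_mirna, standardize_target


@pytest.fixture
def rng():
    return np.random.default_rng(20231209)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture
def make_mirna(rng):
    counter = iter(range(10**6))

    def _make(seq=None, length=20):
        i = next(counter)
        if seq is None:
            seq = random_rna(rng, length)
        return standardize_mirna(seq, id=f"mir-{i}")

    return _make


@pytest.fixture
def make_target(rng):
    counter = iter(range(10**6))

    def _make(seq=None, length=50):
        i = next(counter)
        if seq is None:
            seq = random_rna(rng, length)
        return standardize_target(seq, id=f"tgt-{i}")

    return _make


@pytest.fixture
def random_pairs(make_mirna, make_target):
    def _make(n):
        return [(make_mirna(), make_target()) for _ in range(n)]

    return _make
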