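import random

import numpy as np
import pytest

from amplikit.seqio import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def pyrng():
    return random.Random(20260920)


def make_record(sequence, label="r", abundance=1, ordinal=0, qualities=None):
    return SequenceRecord(
        label=label, sequence=sequence, abundance=abundance,
        ordinal=ordinal, qualities=qualities,
    )


@pytest.fixture
def record_factory():
    return make_record


def random_dna(rand, length):
    return "".join(rand.choice("ACGT") for _ in range(length))


@pytest.fixture
def dna_factory(pyrng):
    return lambda length: random_dna(pyrng, length)
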