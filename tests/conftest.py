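import numpy as np
import pytest

from dnabind import ProteinRecord, standard_groupings
from dnabind.sequence_io import STANDARD_AA


@pytest.fixture(scope="session")
def groupings():
    return standard_groupings()


@pytest.fixture(scope="session")
def hydrophobicity(groupings):
    return groupings[0]


def random_sequence(rng, min_len=1, max_len=500):
    length = int(rng.integers(min_len, max_len + 1))
    letters = rng.choice(list(STANDARD_AA), size=length)
    return "".join(letters)


@pytest.fixture
def random_records():
    """Factory: n random valid records from a seeded generator."""

    def make(n, seed=0, min_len=1, max_len=500):
        rng = np.random.default_rng(seed)
        return [
            ProteinRecord(f"r{i}", random_sequence(rng, min_len, max_len))
            for i in range(n)
        ]

    return make
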