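import numpy as np
import pytest
from hypothesis import settings

from pepskip.sequence_io import ALPHABET, Peptide

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20170924)


@pytest.fixture
def random_peptides(rng):
    """500 random peptides over the full alphabet, lengths 2-30."""
    letters = np.array(list(ALPHABET))
    peps = []
    for i in range(500):
        L = int(rng.integers(2, 31))
        peps.append(Peptide(f"r{i}", "".join(rng.choice(letters, size=L))))
    return peps
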