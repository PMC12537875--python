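import numpy as np
import pytest

from helixevo.seqcore import ALPHABET


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequences_30(rng):
    """1000 random 30-mers for motif-scanner brute-force comparison."""
    letters = np.array(list(ALPHABET))
    return ["".join(letters[rng.integers(0, 20, size=30)]) for _ in range(1000)]
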