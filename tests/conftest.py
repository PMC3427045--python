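import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(20120618)


@pytest.fixture
def random_protein(rng):
    """Seeded uniform-random sequences over the full 20-letter alphabet."""
    def make(length, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        return "".join(alphabet[i] for i in r.integers(0, 20, length))
    return make
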