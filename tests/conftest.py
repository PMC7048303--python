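import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from wgdkit.genetics import SENSE_CODONS

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_codon_pair_factory(rng):
    """Factory for random gap-free CDS pairs (independent uniform codons)."""

    def make(n_codons: int) -> tuple[str, str]:
        idx = rng.integers(0, len(SENSE_CODONS), size=(2, n_codons))
        return tuple("".join(SENSE_CODONS[i] for i in row) for row in idx)

    return make
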