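import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from exat.tables import GenotypeMatrix


@pytest.fixture
def small_matrix():
    """6 subjects (3 cases / 3 controls) x 5 variants, diverse genotypes."""
    rng = np.random.default_rng(123)
    counts = rng.integers(0, 3, size=(6, 5))
    return GenotypeMatrix(
        subject_ids=[f"s{i}" for i in range(6)],
        variant_ids=[f"v{j}" for j in range(5)],
        counts=counts,
        labels=np.array([1, 1, 1, 0, 0, 0]),
    )


@pytest.fixture
def tiny_matrix():
    """4 subjects (2/2) x 3 variants: small enough for exhaustive oracles."""
    counts = np.array([
        [0, 1, 2],
        [1, 0, 0],
        [2, 1, 1],
        [0, 0, 1],
    ])
    return GenotypeMatrix(
        subject_ids=["a", "b", "c", "d"],
        variant_ids=["v0", "v1", "v2"],
        counts=counts,
        labels=np.array([1, 1, 0, 0]),
    )
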