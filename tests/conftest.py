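import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gerrophylo.tree import Tree


@pytest.fixture
def cherry() -> Tree:
    """Two tips, both branches 0.5."""
    return Tree([-1, 0, 0], [0.0, 0.5, 0.5], [None, "a", "b"])


@pytest.fixture
def balanced4() -> Tree:
    """((a,b),(c,d)) with unit-ish branch lengths."""
    return Tree(
        [-1, 0, 1, 1, 0, 4, 4],
        [0.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
        [None, None, "a", "b", None, "c", "d"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
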