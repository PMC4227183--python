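import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from crackseq import LibraryPair


@pytest.fixture
def pair_equal() -> LibraryPair:
    return LibraryPair("non-cracking", "cracking", 100_000, 100_000)


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    """Five genes; g0 is strongly up in library 2, the rest unchanged."""
    return pd.DataFrame(
        {
            "unigene_id": [f"g{k}" for k in range(5)],
            "count_1": [0, 30, 30, 30, 30],
            "count_2": [60, 30, 30, 30, 30],
        }
    )


@pytest.fixture
def toy_lengths() -> dict:
    return {f"g{k}": 1000 for k in range(5)}
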