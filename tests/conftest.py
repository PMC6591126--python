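import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def toy_counts():
    """5 samples x 4 OTUs with hand-set counts."""
    return pd.DataFrame(
        {
            "otu1": [10, 0, 3, 7, 0],
            "otu2": [5, 5, 5, 5, 5],
            "otu3": [0, 0, 0, 12, 0],
            "otu4": [85, 95, 92, 76, 95],
        },
        index=[f"s{i}" for i in range(1, 6)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
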