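import numpy as np
import pandas as pd
import pytest

import dcakit as dk


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def confusion3():
    """Type 1 never confused; types 2 and 3 swap with probability 0.3."""
    return dk.theoretical_confusion()


@pytest.fixture
def small_counts():
    return dk.CellCountTable(
        ["s1", "s2", "s3", "s4"],
        ["A", "B", "C"],
        np.array([[30, 50, 20], [25, 55, 20], [40, 40, 20], [35, 45, 20]]),
    )


@pytest.fixture
def two_group_design():
    return dk.DesignMatrix(
        ["s1", "s2", "s3", "s4"],
        pd.DataFrame({"condition": [0.0, 0.0, 1.0, 1.0]}),
        tested=["condition"],
    )
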