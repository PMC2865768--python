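import numpy as np
import pandas as pd
import pytest

from grnrules.decision_table import DecisionTable


@pytest.fixture
def two_block_table():
    """Worked example: block 'low' = 5 Tumor + 1 Normal, 'high' = 1 Tumor + 3 Normal."""
    df = pd.DataFrame(
        {
            "g": ["low"] * 6 + ["high"] * 4,
            "D": ["Tumor"] * 5 + ["Normal"] + ["Tumor"] + ["Normal"] * 3,
        },
        index=[f"s{i}" for i in range(10)],
    )
    return DecisionTable(data=df, decision_attribute="D")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def random_discrete_table(rng, max_samples=12, max_attrs=4):
    """Random categorical decision table for oracle comparisons."""
    n = int(rng.integers(2, max_samples + 1))
    k = int(rng.integers(1, max_attrs + 1))
    data = {
        f"a{j}": rng.choice(["x", "y", "z"][: int(rng.integers(1, 4))], size=n)
        for j in range(k)
    }
    data["D"] = rng.choice(["Tumor", "Normal"], size=n)
    df = pd.DataFrame(data, index=[f"s{i}" for i in range(n)])
    return DecisionTable(data=df, decision_attribute="D")
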