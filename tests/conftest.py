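import numpy as np
import pandas as pd
import pytest

from metabreduce import MetaboliteTable, SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_table():
    """3 metabolites x 4 samples over 2 regions of one origin + 1 of another."""
    values = np.array(
        [
            [0.0, 0.5, 3.0, 1.0],
            [2.0, 2.1, 0.0, 4.0],
            [0.01, 0.02, 0.03, 0.04],
        ]
    )
    meta = pd.DataFrame(
        {
            "origin": ["Manado", "Manado", "Manado", "Bali"],
            "region": ["M1", "M1", "M2", "B1"],
            "replicate": [1, 2, 1, 1],
        }
    )
    return MetaboliteTable(values, ["glucose", "fructose", "eugenol"], meta)


@pytest.fixture
def study_table():
    """Default-shaped synthetic study: 4 origins x 3 regions x 8 replicates."""
    table, truth = generate(SyntheticConfig(seed=11))
    return table, truth
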