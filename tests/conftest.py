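import numpy as np
import pandas as pd
import pytest

from eimbiome.containers import CountTable
from eimbiome.synthetic import SimulationParams, generate_community


@pytest.fixture
def toy_counts() -> CountTable:
    """4 biological samples x 3 ASVs with simple hand-checkable counts."""
    return CountTable(
        pd.DataFrame(
            [[10, 0, 5], [2, 2, 6], [8, 1, 1], [0, 4, 4]],
            index=["S1", "S2", "S3", "S4"],
            columns=["A", "B", "C"],
        )
    )


@pytest.fixture
def toy_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": ["EIM", "EIM", "C", "C"],
            "subtype": ["CD", "UC", "CD", "UC"],
            "surgery": [True, False, False, True],
            "is_negative_control": [False] * 4,
        },
        index=["S1", "S2", "S3", "S4"],
    )


@pytest.fixture(scope="session")
def small_community():
    """Medium synthetic community reused by several slow-ish tests."""
    params = SimulationParams(
        n_samples_per_group=(40, 40),
        n_asvs=60,
        module_spec=[(5, 0.8)],
        effect_spec=[(10, 3.0, 0.0)],
        contaminant_spec=[(20, 25.0, 0.05)],
        seed=11,
    )
    counts, meta, truth = generate_community(params)
    return params, counts, meta, truth


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(test_seed)
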