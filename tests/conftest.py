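import numpy as np
import pandas as pd
import pytest

from metabotype import (
    FeatureTable,
    default_preclinical_spec,
    simulate_preclinical,
)


def make_table(values, groups=None, blocks=None, is_qc=None, cohort="preclinical"):
    """Small FeatureTable from a 2-D array or DataFrame."""
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=[f"s{i}" for i in range(len(values))],
            columns=[f"m{j}" for j in range(np.asarray(values).shape[1])],
        )
    n = len(values)
    samples = pd.DataFrame(
        {
            "cohort": cohort,
            "group": groups if groups is not None else [""] * n,
            "block": blocks if blocks is not None else [1] * n,
            "is_qc": is_qc if is_qc is not None else [False] * n,
        },
        index=values.index,
    )
    return FeatureTable(samples, values)


@pytest.fixture(scope="session")
def preclinical_table():
    """One seeded preclinical cohort shared by read-only tests."""
    table, truth = simulate_preclinical(default_preclinical_spec(seed=7))
    return table, truth
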