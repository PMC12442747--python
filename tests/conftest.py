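import numpy as np
import pytest

from diagest.fixtures import ct_example_counts, ct_example_records
from diagest.study_data import (
    EstimandSpec,
    StratifiedCounts,
    StratumCell,
)


@pytest.fixture(scope="session")
def ct_records():
    return ct_example_records()


@pytest.fixture(scope="session")
def ct_counts():
    return ct_example_counts()


def make_spec(strategy_map=None, measures=("sensitivity", "specificity"), **kwargs):
    """Minimal valid estimand spec for tests."""
    payload = {
        "target_condition": {"label": "target"},
        "index_test": {"rule": "rule"},
        "accuracy_measures": list(measures),
        "strategy_map": strategy_map or {},
        **kwargs,
    }
    return EstimandSpec.model_validate(payload)


def random_counts(rng: np.random.Generator, max_cell: int = 50) -> StratifiedCounts:
    """A random 2x2x2 table with every stratum non-empty."""
    c = rng.integers(0, max_cell + 1, size=8)
    # keep each of the four condition x IE strata non-empty so every
    # strategy's denominator is defined
    cells = []
    for j in range(4):
        pos, neg = int(c[2 * j]), int(c[2 * j + 1])
        if pos + neg == 0:
            pos = 1
        cells.append(StratumCell(positive=pos, negative=neg))
    return StratifiedCounts(
        diseased_without_ie=cells[0],
        diseased_with_ie=cells[1],
        healthy_without_ie=cells[2],
        healthy_with_ie=cells[3],
        event_type="ie",
    )
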