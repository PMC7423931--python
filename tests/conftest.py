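import numpy as np
import pandas as pd
import pytest

from snowflux import load_truth


@pytest.fixture(scope="session")
def truth():
    return load_truth()


@pytest.fixture(scope="session")
def incubation_records(truth):
    """One default-scenario sub-zero incubation draw (mechanistic generator)."""
    from snowflux import simulate_incubation
    records, full = simulate_incubation(truth, temperatures=(-10, -6, -2), seed=301)
    return records, full


@pytest.fixture(scope="session")
def glucose_records(truth):
    from snowflux import simulate_glucose_experiment
    records, info = simulate_glucose_experiment(truth, seed=17)
    return records, info
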