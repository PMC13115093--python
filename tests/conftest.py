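import numpy as np
import pytest

from teacolloid import reference, synthetic_data


@pytest.fixture()
def closeness_table():
    """The reported 30-row TOPSIS outcome (d+, d-, C, rank)."""
    return reference.closeness_table()


@pytest.fixture()
def condition_records():
    """A seeded 30-row synthetic separation-condition table."""
    return synthetic_data.gen_condition_table(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
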