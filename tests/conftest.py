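import numpy as np
import pytest

from promkit.synthetic import BankSpec, generate_item_bank, simulate_responses


@pytest.fixture(scope="session")
def bank13():
    """A 13-item, 5-category bank used across calibration tests."""
    return generate_item_bank(BankSpec(13, name="b13"), seed=101)


@pytest.fixture(scope="session")
def responses2000(bank13):
    """n=2000 GRM responses from bank13 with theta ~ N(0,1)."""
    rng = np.random.default_rng(7)
    theta = rng.normal(size=2000)
    resp = simulate_responses(bank13, theta, seed=42)
    return resp, theta


@pytest.fixture(scope="session")
def small_bank():
    """A tiny 4-item, 3-category bank for enumeration oracles."""
    return generate_item_bank(BankSpec(4, n_categories=3, name="s"), seed=5)
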