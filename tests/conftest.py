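import numpy as np
import pytest

from leamq import CohortConfig, default_key, generate_cohort


@pytest.fixture(scope="session")
def key():
    return default_key()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort, shared across read-only tests."""
    return generate_cohort(CohortConfig(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def baseline_answers(key, version="v2"):
    """Answers whose *adjusted* code is 0 for every item (raw max for
    reverse-coded items)."""
    return {
        it.item_id: (it.max_code if it.reverse_coded else 0)
        for it in key.items_for(version)
    }
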