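import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from igtpain import build_payoff_scheme


@pytest.fixture(scope="session")
def scheme():
    return build_payoff_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_session_trials(rng, n=20):
    """Random (choice, net) pairs with realistic euro magnitudes."""
    choices = rng.integers(0, 4, size=n)
    nets = rng.choice([100.0, 50.0, -150.0, -1150.0, -200.0, 0.0], size=n)
    return list(zip((int(c) for c in choices), (float(x) for x in nets)))
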