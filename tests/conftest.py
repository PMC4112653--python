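import numpy as np
import pytest

from glueear import default_deck, run_psa


@pytest.fixture(scope="session")
def deck():
    return default_deck()


@pytest.fixture(scope="session")
def means(deck):
    """Deterministic parameter vector at the analytic prior means."""
    return deck.means()


@pytest.fixture(scope="session")
def psa10k(deck):
    """One full-size PSA shared across tests (10,000 draws, fixed seed)."""
    return run_psa(deck, n_sims=10_000, seed=12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
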