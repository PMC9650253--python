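import warnings

import pytest

from omnirule.apriori import Transactions
from omnirule.synth import SynthConfig, generate_dataset


@pytest.fixture()
def toy_transactions() -> Transactions:
    """The four-basket worked example used throughout the rule tests."""
    return Transactions.from_itemsets(
        [{"A", "B"}, {"A", "C"}, {"A", "B", "C"}, {"B", "C"}]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic study reused by read-only tests."""
    cfg = SynthConfig(
        n_samples=48, n_nmr_features=32, n_taxa=12, k_clusters=3,
        separation=6.0, n_discriminative=3, seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def no_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
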