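import numpy as np
import pandas as pd
import pytest

from proxyrare import simulate as sim


@pytest.fixture(scope="session")
def small_dataset():
    """A 3,000-participant synthetic biobank shared across read-only tests."""
    spec = sim.VariantSpec(n_common=60, n_rare=90, n_ultra_rare=120, n_genes=12)
    return sim.simulate_dataset(n=3000, spec=spec, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def feature_columns():
    return [n for n, _, _, _ in sim.FEATURE_PANEL]
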