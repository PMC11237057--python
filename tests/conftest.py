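import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mtqsar.synthetic import worked_fixture, worked_fixture_expected

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def fixture_data():
    """The tiny worked dataset: (records, raw descriptor table); fresh per test."""
    return worked_fixture()


@pytest.fixture(scope="session")
def fixture_golden():
    """Hand/oracle-computed golden values for the worked dataset."""
    return worked_fixture_expected()


@pytest.fixture
def two_class_data():
    """Separable two-class Gaussian data: (X DataFrame, y 0/1), seed-fixed."""

    def make(n=200, p=5, n_informative=2, effect=3.0, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < 0.5).astype(int)
        X = rng.normal(size=(n, p))
        X[:, :n_informative] += np.where(y[:, None] == 1, effect / 2, -effect / 2)
        cols = [f"f{i}" for i in range(p)]
        return pd.DataFrame(X, columns=cols), y

    return make
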