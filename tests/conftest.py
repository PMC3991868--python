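import numpy as np
import pytest

from udopt import data, design, rsm
from udopt.data import Dataset, ResponseRecord


@pytest.fixture(scope="session")
def train_table() -> Dataset:
    return data.load_training_table()


@pytest.fixture(scope="session")
def test_table() -> Dataset:
    return data.load_test_table()


@pytest.fixture(scope="session")
def space():
    return design.reference_space()


@pytest.fixture(scope="session")
def refit_model(train_table):
    """The 8-term quadratic refit on the bundled training means."""
    return rsm.fit_quadratic(train_table)


@pytest.fixture(scope="session")
def reference_model():
    """The rounded reference-equation coefficients."""
    return rsm.reference_equation()


def make_dataset(X, y, space, role="train"):
    records = [
        ResponseRecord(i + 1, tuple(x), float(v), 0.0, 1) for i, (x, v) in enumerate(zip(X, y))
    ]
    return Dataset(records=records, role=role, space=space)


@pytest.fixture(scope="session")
def grid_dataset(space):
    """Noiseless 5x5x5 grid responses from a known concave quadratic."""
    lo, hi = space.box()
    axes = [np.linspace(l, h, 5) for l, h in zip(lo, hi)]
    X = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
    truth = rsm.reference_equation()
    return make_dataset(X, truth.predict(X), space), truth
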