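import numpy as np
import pandas as pd
import pytest

import hematrisk as hr


@pytest.fixture(scope="session")
def default_config():
    return hr.default_config()


@pytest.fixture(scope="session")
def cohort(default_config):
    """One calibrated synthetic cohort (exact clinical proportions)."""
    return hr.generate_cohort(default_config, seed=11)


@pytest.fixture(scope="session")
def fixture_tables():
    """The published cluster x characteristic cross-tables."""
    return {
        name: hr.ContingencyTable.from_fixture(name)
        for name in ("final_diagnosis", "proteinuria", "stage", "grade", "cytology")
    }


def make_matrix(values, ids=None, cols=None) -> hr.BiomarkerMatrix:
    values = np.asarray(values, dtype=float)
    ids = ids or [f"P{i}" for i in range(values.shape[0])]
    cols = cols or [f"b{j}" for j in range(values.shape[1])]
    return hr.BiomarkerMatrix(pd.DataFrame(values, index=ids, columns=cols))


@pytest.fixture
def planted_two_clouds():
    """Two tight, far-separated point clouds: trivially stable structure."""
    rng = np.random.default_rng(42)
    a = np.abs(rng.normal(1.0, 0.01, size=(15, 4)))
    b = np.abs(rng.normal(100.0, 1.0, size=(15, 4)))
    labels = np.array([0] * 15 + [1] * 15)
    return make_matrix(np.vstack([a, b])), labels


def planted_signal_cohort(seed: int, n: int = 400, shift: float = 0.8):
    """Binary cohort where exactly one biomarker per block carries signal.

    Log-normal features; informative markers get a log-scale class shift.
    Returns (matrix, labels, clustering, informative-marker set).
    """
    rng = np.random.default_rng(seed)
    y = np.arange(n) < n // 2
    cols, clusters = {}, []
    for b in range(7):
        sig, noise = f"sig{b}", f"noise{b}"
        clusters.append(sorted([sig, noise]))
        cols[sig] = np.exp(rng.normal(0.0, 1.0, n) + shift * y)
        cols[noise] = np.exp(rng.normal(0.0, 1.0, n))
    X = pd.DataFrame(cols, index=[f"P{i}" for i in range(n)])
    labels = pd.Series(y, index=X.index)
    return (
        hr.BiomarkerMatrix(X),
        labels,
        hr.BiomarkerClustering(clusters),
        {f"sig{b}" for b in range(7)},
    )
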