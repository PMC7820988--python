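import numpy as np
import pytest

from selstab import Dataset


def make_linear_dataset(N=60, seed=0, beta=(1.2, 0.5, 0.0, 0.0, 0.0),
                        corr=0.3, group_last=False, sigma=1.0):
    """Small correlated linear-regression dataset for selection tests.

    ``group_last=True`` adds a two-column term (the last two columns form
    one group).
    """
    rng = np.random.default_rng(seed)
    k = len(beta)
    L = np.linalg.cholesky(corr * np.ones((k, k)) + (1 - corr) * np.eye(k))
    X = rng.standard_normal((N, k)) @ L.T
    y = X @ np.asarray(beta) + sigma * rng.standard_normal(N)
    cols = [f"x{i + 1}" for i in range(k)]
    if group_last:
        terms = {c: [i] for i, c in enumerate(cols[:-2])}
        terms["grp"] = [k - 2, k - 1]
    else:
        terms = {c: [i] for i, c in enumerate(cols)}
    return Dataset(X, y, terms, "linear", columns=cols)


@pytest.fixture
def toy_linear():
    return make_linear_dataset(N=80, seed=7)


@pytest.fixture
def toy_linear_grouped():
    return make_linear_dataset(N=80, seed=11, group_last=True)
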