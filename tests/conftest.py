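import numpy as np
import pytest

from dfsc import SurvivalDataset


def make_dataset(time, event, X=None, n_genes=1, labeled_mask=None, seed=0):
    """Small labeled dataset with optional expression matrix."""
    time = np.asarray(time, dtype=float)
    n = len(time)
    if X is None:
        X = np.random.default_rng(seed).standard_normal((n, n_genes))
    X = np.asarray(X, dtype=float)
    return SurvivalDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(X.shape[1])],
        X=X,
        time=time,
        event=np.asarray(event),
        labeled_mask=labeled_mask,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_censored(rng, n, with_ties=False):
    """Random right-censored outcome vectors plus risk scores."""
    t = rng.exponential(1.0, n)
    if with_ties:
        t = np.round(t, 1)
    e = rng.integers(0, 2, n)
    if e.sum() == 0:
        e[rng.integers(n)] = 1
    risk = rng.standard_normal(n)
    return t, e, risk
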