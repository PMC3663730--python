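import numpy as np
import pytest

from cpba.model import CPBAModel


def random_instance(rng, n=8, K=2, kind="poisson"):
    """A random valid (A, model) pair, far from any fixed point."""
    c = rng.integers(1, K + 1, size=n)
    # ensure every proper cluster is occupied
    c[:K] = np.arange(1, K + 1)
    p = rng.uniform(0.5, 2.0, size=n)
    R = np.eye(K + 1)
    for a in range(1, K + 1):
        for b in range(a + 1, K + 1):
            R[a, b] = R[b, a] = rng.uniform(0.05, 0.9)
    if kind == "poisson":
        mu = R[np.ix_(c, c)] * np.outer(p, p)
        A = rng.poisson(mu).astype(float)
    else:
        A = rng.uniform(0.0, 1.0, size=(n, n))
    A = np.triu(A, 1)
    A = A + A.T
    model = CPBAModel(c=c, p=p, R=R, objective_kind=kind)
    return A, model


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
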