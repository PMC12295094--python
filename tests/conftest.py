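import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from bayesem import BasisConfig, Hyperparameters, RegressionData


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def scalar_line_data():
    """M=1 basis psi(x)=x on X=[1,2], T=[1,2]: the hand-computable instance
    with posterior C=1/6, m=5/6 under eta=1, lam=1, mu=0."""
    X = np.array([[1.0], [2.0]])
    return RegressionData(X, np.array([1.0, 2.0]), X.copy())


def random_instance(rng, n=12, m=3, eta_scale=1.0):
    """A small random regression instance with well-scaled hyperparameters."""
    X = rng.uniform(-1, 1, size=(n, m))
    Psi = X.copy()
    T = rng.normal(0.0, 1.0, size=n)
    hp = Hyperparameters(
        eta=np.exp(rng.uniform(-1.5, 1.5, size=m)) * eta_scale,
        lam=float(np.exp(rng.uniform(-1.5, 1.5))),
        mu=rng.normal(0.0, 1.0, size=m),
    )
    return RegressionData(X, T, Psi), hp
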