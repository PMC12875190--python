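import numpy as np
import pytest


def make_problem(n=30, p=3, d=1, beta=0.0, seed=0, design="normal"):
    """A small regression problem with an intercept column in Z."""
    import robustpalmrt as rp

    rng = np.random.default_rng(seed)
    draw = rng.standard_cauchy if design == "cauchy" else rng.standard_normal
    Z = np.column_stack([np.ones(n), draw((n, p - 1))]) if p > 1 else np.ones((n, 1))
    X = draw((n, d))
    Y = X @ (beta * np.ones(d)) + rng.standard_normal(n)
    return rp.RegressionProblem(Y, X, Z)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
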