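"""Classical comparator tests.

Both baselines rest on normality or asymptotics and serve as reference
points for the permutation tests: the partial F-test for a location
effect, and the Koenker-studentized Breusch-Pagan test for
heteroskedasticity driven by the covariate of interest.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from .core import RegressionProblem

__all__ = ["partial_f_test", "koenker_bp_test"]


def partial_f_test(problem: RegressionProblem) -> float:
    """Nested-model F-test of H0: beta = 0, comparing Y ~ Z to Y ~ X + Z.

    Returns the upper-tail p-value of the F statistic with
    (d, n - d - p) degrees of freedom.  If both residual sums of squares
    are zero (Y fits the null model exactly) the statistic carries no
    information and p = 1 is returned.
    """
    Y, X, Z = problem.Y, problem.X, problem.Z
    n, d, p = problem.n, problem.d, problem.p
    if n <= d + p:
        raise ValueError("need n > d + p for the F-test")
    full = np.concatenate([X, Z], axis=1)
    if np.linalg.matrix_rank(full) < d + p:
        raise ValueError("full design [X, Z] is rank deficient")
    rss1 = float(np.sum(_lstsq_resid(full, Y) ** 2))
    rss0 = float(np.sum(_lstsq_resid(Z, Y) ** 2))
    df2 = n - d - p
    if rss1 <= 0:
        return 1.0 if rss0 <= 0 else 0.0
    f = (rss0 - rss1) / d / (rss1 / df2)
    return float(stats.f.sf(f, d, df2))


def _lstsq_resid(design, y):
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def koenker_bp_test(problem: RegressionProblem, aux: str = "x") -> float:
    """Koenker-studentized Breusch-Pagan test for heteroskedasticity.

    Fits Y on [X, Z] by OLS and regresses the squared residuals on the
    auxiliary set: an intercept plus X (``aux="x"``, the default, since
    the dispersion model places heteroskedasticity in X) or an intercept
    plus [X, Z] (``aux="xz"``).  The studentized statistic n * R^2 of the
    auxiliary regression is referred to a chi-square distribution with
    one degree of freedom per auxiliary slope.
    """
    Y, X, Z = problem.Y, problem.X, problem.Z
    full = np.concatenate([X, Z], axis=1)
    if np.linalg.matrix_rank(full) < problem.d + problem.p:
        raise ValueError("full design [X, Z] is rank deficient")
    resid = _lstsq_resid(full, Y)
    if np.ptp(resid**2) == 0:
        return 1.0
    if aux == "x":
        slopes = X
    elif aux == "xz":
        # drop constant columns of Z (the intercept is added below)
        keep = np.ptp(Z, axis=0) > 0
        slopes = np.concatenate([X, Z[:, keep]], axis=1)
    else:
        raise ValueError("aux must be 'x' or 'xz'")
    exog_het = np.column_stack([np.ones(problem.n), slopes])
    lm, lm_pvalue, _, _ = het_breuschpagan(resid, exog_het, robust=True)
    return float(lm_pvalue)
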