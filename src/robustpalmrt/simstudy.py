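"""Synthetic-data generators and the Monte-Carlo study harness.

The generators emulate the benchmark conditions used to characterize the
permutation tests: heavy-tailed Cauchy(0,1) covariates with an intercept
column, and error laws ranging from Gaussian to pathological (a
multinomial+normal mixture placing one observation at N(+-1e4, 1)).  The
harness estimates type I error and power over replicated datasets, with
per-replicate seeds derived from a single master seed so that results are
independent of execution order, and calibrates effect sizes so the
classical F-test attains a prescribed power (giving the permutation tests
a fair, fixed yardstick).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .baselines import koenker_bp_test, partial_f_test
from .core import RegressionProblem, run_test, sample_permutations
from .dispersion import DispersionSpec, run_dispersion_test
from .exceptions import CalibrationError
from .evaluators import EVALUATORS
from .fitters import FITTERS

__all__ = [
    "ScenarioConfig",
    "gen_design",
    "gen_errors",
    "gen_location_response",
    "gen_dispersion_response",
    "calibrate_beta",
    "run_study",
    "ERROR_LAWS",
    "DESIGN_LAWS",
]

#: Location of the gross outlier in the multinomial+normal error law.
OUTLIER_CENTER = 1e4

ERROR_LAWS = ("normal", "t3", "cauchy", "multinomial_normal", "lognormal")
DESIGN_LAWS = ("cauchy", "normal", "t3", "anova_balanced")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation cell: data-generating process, method, and budget."""

    n: int
    p: int = 6
    d: int = 1
    error_law: str = "normal"
    design_law: str = "cauchy"
    beta: float = 0.0
    B: int = 999
    alpha: float = 0.05
    n_reps: int = 1000
    seed: int = 0
    method: str = "huber-huber"
    dispersion: bool = False

    def __post_init__(self):
        if self.n <= self.p + self.d:
            raise ValueError("need n > p + d")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.error_law not in ERROR_LAWS:
            raise ValueError(f"unknown error law {self.error_law!r}; choose from {ERROR_LAWS}")
        if self.design_law not in DESIGN_LAWS:
            raise ValueError(f"unknown design law {self.design_law!r}; choose from {DESIGN_LAWS}")


def _law_draw(rng: np.random.Generator, law: str, size) -> np.ndarray:
    if law == "normal":
        return rng.standard_normal(size)
    if law == "t3":
        return rng.standard_t(3, size)
    if law == "cauchy":
        return rng.standard_cauchy(size)
    if law == "lognormal":
        return np.exp(rng.standard_normal(size))
    raise ValueError(f"unknown law {law!r}")


def gen_design(n: int, p: int, d: int, design_law: str = "cauchy", seed=0):
    """Generate the covariate of interest X (n x d) and controls Z (n x p).

    Z's first column is an intercept of ones; all remaining entries of X
    and Z are i.i.d. draws from ``design_law``.  The ``anova_balanced``
    law fills each column with a balanced two-level factor (+-1, n/2
    each, in random order).
    """
    rng = np.random.default_rng(seed)
    if design_law not in DESIGN_LAWS:
        raise ValueError(f"unknown design law {design_law!r}; choose from {DESIGN_LAWS}")
    if design_law == "anova_balanced":
        def draw(size):
            cols = []
            for _ in range(size[1]):
                lv = np.repeat([-1.0, 1.0], [size[0] // 2, size[0] - size[0] // 2])
                cols.append(rng.permutation(lv))
            return np.column_stack(cols) if cols else np.empty((size[0], 0))
    else:
        def draw(size):
            return _law_draw(rng, design_law, size)
    X = draw((n, d))
    Z = np.column_stack([np.ones(n), draw((n, p - 1))]) if p > 1 else np.ones((n, 1))
    return X, Z


def gen_errors(n: int, error_law: str, seed=0) -> np.ndarray:
    """Draw an error vector from the named law.

    ``multinomial_normal`` draws n-1 i.i.d. N(0,1) entries and replaces
    one uniformly chosen entry by N(s * 1e4, 1) with the sign s = +-1
    equiprobable -- a single gross outlier.
    """
    rng = np.random.default_rng(seed)
    if error_law == "multinomial_normal":
        eps = rng.standard_normal(n)
        idx = rng.integers(n)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        eps[idx] = rng.normal(sign * OUTLIER_CENTER, 1.0)
        return eps
    if error_law in ERROR_LAWS:
        return _law_draw(rng, error_law, n)
    raise ValueError(f"unknown error law {error_law!r}; choose from {ERROR_LAWS}")


def gen_location_response(X, Z, beta, errors, theta=None) -> np.ndarray:
    """Response under the location model Y = X beta + Z theta + eps.

    theta defaults to zero: the tests are invariant to shifts by Z theta,
    so the choice is without loss of generality (and is covered by an
    end-to-end invariance test)."""
    X = np.atleast_2d(np.asarray(X, dtype=float).T).T
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    Y = X @ beta + np.asarray(errors, dtype=float)
    if theta is not None:
        Y = Y + np.asarray(Z, dtype=float) @ np.asarray(theta, dtype=float)
    return Y


def gen_dispersion_response(X_binary, Z, beta, errors, theta=None) -> np.ndarray:
    """Response under the dispersion model Y_i = Z_i theta + (1 + beta X_i) eps_i.

    X binary in {0,1}: cases (X=1) have their noise scaled by (1 + beta).
    """
    if beta <= -1:
        raise ValueError("beta must exceed -1 (noise scale must stay positive)")
    x = np.asarray(X_binary, dtype=float).ravel()
    Y = (1.0 + beta * x) * np.asarray(errors, dtype=float)
    if theta is not None:
        Y = Y + np.asarray(Z, dtype=float) @ np.asarray(theta, dtype=float)
    return Y


def _balanced_binary(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.permutation(np.repeat([0.0, 1.0], [n - n // 2, n // 2]))


def _location_method(method: str):
    """Split "fitter-evaluator" method names; returns None for baselines."""
    if "-" in method:
        f, e = method.split("-", 1)
        if f in FITTERS and e in EVALUATORS:
            return f, e
    return None


def _one_location_rep(cfg: ScenarioConfig, ss: np.random.SeedSequence) -> float:
    rng = np.random.default_rng(ss)
    dseed, eseed, pseed = (int(s) for s in rng.integers(2**31, size=3))
    X, Z = gen_design(cfg.n, cfg.p, cfg.d, cfg.design_law, dseed)
    eps = gen_errors(cfg.n, cfg.error_law, eseed)
    Y = gen_location_response(X, Z, cfg.beta, eps)
    problem = RegressionProblem(Y, X, Z)
    pair = _location_method(cfg.method)
    if pair is not None:
        perms = sample_permutations(cfg.n, cfg.B, pseed)
        return run_test(problem, pair[0], pair[1], perms, cfg.alpha).pvalue
    if cfg.method == "ftest":
        return partial_f_test(problem)
    raise ValueError(f"unknown location method {cfg.method!r}")


def _one_dispersion_rep(cfg: ScenarioConfig, ss: np.random.SeedSequence) -> float:
    rng = np.random.default_rng(ss)
    dseed, eseed, pseed = (int(s) for s in rng.integers(2**31, size=3))
    _, Z = gen_design(cfg.n, cfg.p, cfg.d, cfg.design_law, dseed)
    x = _balanced_binary(cfg.n, rng)
    eps = gen_errors(cfg.n, cfg.error_law, eseed)
    Y = gen_dispersion_response(x, Z, cfg.beta, eps)
    problem = RegressionProblem(Y, x, Z)
    if cfg.method == "dispersion":
        perms = sample_permutations(cfg.n, cfg.B, pseed)
        return run_dispersion_test(problem, perms, DispersionSpec(), cfg.alpha).pvalue
    if cfg.method == "bptest":
        return koenker_bp_test(problem)
    if cfg.method == "ftest":
        return partial_f_test(problem)
    raise ValueError(f"unknown dispersion method {cfg.method!r}")


def _run_scenario(cfg: ScenarioConfig, n_jobs: int = 1) -> dict:
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_reps)
    rep = _one_dispersion_rep if cfg.dispersion else _one_location_rep

    def safe(ss):
        try:
            return rep(cfg, ss)
        except Exception:
            return np.nan

    if n_jobs == 1:
        pvals = np.array([safe(ss) for ss in seeds])
    else:
        pvals = np.array(Parallel(n_jobs=n_jobs)(delayed(safe)(ss) for ss in seeds))
    n_fail = int(np.isnan(pvals).sum())
    if n_fail > 0.01 * cfg.n_reps:
        raise RuntimeError(
            f"{n_fail}/{cfg.n_reps} replicates failed in scenario {cfg}"
        )
    ok = pvals[~np.isnan(pvals)]
    rate = float(np.mean(ok <= cfg.alpha))
    row = asdict(cfg)
    row.update(
        rejection_rate=rate,
        mc_se=float(np.sqrt(rate * (1 - rate) / ok.size)),
        n_fail=n_fail,
    )
    return row


def run_study(configs: Sequence[ScenarioConfig], n_jobs: int = 1) -> pd.DataFrame:
    """Run each scenario and return a tidy table of rejection rates.

    One row per scenario with the full configuration echoed plus
    ``rejection_rate``, its binomial Monte-Carlo standard error ``mc_se``
    and the count of failed replicates.  Per-replicate seeds are spawned
    deterministically from each scenario's seed, so serial and parallel
    runs produce identical tables.
    """
    return pd.DataFrame([_run_scenario(cfg, n_jobs=n_jobs) for cfg in configs])


def _f_power_curve(n: int, p: int, alpha: float, n_reps: int, seed,
                   error_law: str = "normal", design_law: str = "cauchy"):
    """Closed-form F-test power as a function of beta on a fixed set of
    replicate datasets (common random numbers).

    For each replicate, residualizing X and eps on Z reduces the partial
    F statistic at effect size beta to a rational function of three
    scalars, so the power curve can be evaluated exactly on the shared
    draws without refitting.
    """
    root = np.random.SeedSequence(seed)
    a = np.empty(n_reps)
    bb = np.empty(n_reps)
    c = np.empty(n_reps)
    for i, ss in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(ss)
        dseed, eseed = (int(s) for s in rng.integers(2**31, size=2))
        X, Z = gen_design(n, p, 1, design_law, dseed)
        eps = gen_errors(n, error_law, eseed)
        coefx, *_ = np.linalg.lstsq(Z, X[:, 0], rcond=None)
        coefe, *_ = np.linalg.lstsq(Z, eps, rcond=None)
        xt = X[:, 0] - Z @ coefx
        et = eps - Z @ coefe
        a[i] = xt @ xt
        bb[i] = xt @ et
        c[i] = et @ et
    df2 = n - p - 1
    fcrit = stats.f.isf(alpha, 1, df2)

    def power(beta: float) -> float:
        # residualized response ~ xt*beta + et
        sxy = a * beta + bb
        syy = a * beta**2 + 2 * bb * beta + c
        rss1 = syy - sxy**2 / a
        f = (syy - rss1) / (rss1 / df2)
        return float(np.mean(f > fcrit))

    return power


def calibrate_beta(target_power: float, scenario: ScenarioConfig,
                   tol: float = 0.02, n_reps_eval: int = 2000,
                   max_beta: float = 1e6) -> float:
    """Find beta >= 0 at which the partial F-test attains ``target_power``.

    Bisection on beta against a Monte-Carlo power curve evaluated with
    common random numbers (the same ``n_reps_eval`` datasets reused at
    every beta), so the curve is a deterministic nondecreasing step
    function and bisection terminates cleanly.  Stops when the power at
    the midpoint is within ``tol`` of the target.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")
    power = _f_power_curve(scenario.n, scenario.p, scenario.alpha,
                           n_reps_eval, scenario.seed,
                           scenario.error_law, scenario.design_law)
    lo, p_lo = 0.0, power(0.0)
    if abs(p_lo - target_power) <= tol:
        return lo
    if p_lo > target_power:
        raise CalibrationError(
            f"power at beta=0 is {p_lo:.3f}, already above the target {target_power}"
        )
    hi = min(1.0, max_beta)
    while power(hi) < target_power:
        hi *= 2.0
        if hi > max_beta:
            raise CalibrationError(
                f"could not bracket target power {target_power} below beta={max_beta}"
            )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p_mid = power(mid)
        if abs(p_mid - target_power) <= tol:
            return mid
        if p_mid < target_power:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9 * max(1.0, hi):
            break
    return 0.5 * (lo + hi)
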