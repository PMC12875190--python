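"""DispersionPALMRT: a permutation test for case/control differences in
conditional dispersion.

Location tests ask whether a binary covariate shifts the center of the
response; this test asks whether it widens the response distribution.  The
dispersion of each subject is summarized by the fitted conditional 80%
inter-quantile range: two quantile regressions of Y on [X, Z, Z_pi] (at
q_low = 0.10 and q_high = 0.90) give per-subject fitted spreads
yhat_high,i - yhat_low,i, which are averaged within the case and control
groups.  The evaluation score

    omega = -log( mean case spread / mean control spread )

is smaller when cases are relatively more dispersed, so the paired
permutation comparison is one-sided for increased case dispersion.  A
two-sided variant (omega = -|log ratio|) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _linalg
from .core import PermutationSet, RegressionProblem, TestResult, pvalue_from_scores
from .exceptions import DegenerateDispersionError
from .fitters import _augment

__all__ = [
    "DispersionSpec",
    "GroupedQuantileFit",
    "fit_quantile_pair",
    "dispersion_omega",
    "run_dispersion_test",
]


@dataclass(frozen=True)
class DispersionSpec:
    """Quantile pair defining the conditional inter-quantile range."""

    q_low: float = 0.10
    q_high: float = 0.90
    tol: float = 1e-8
    max_iter: int = 50

    def __post_init__(self):
        if not 0.0 < self.q_low < self.q_high < 1.0:
            raise ValueError("require 0 < q_low < q_high < 1")


@dataclass(frozen=True)
class GroupedQuantileFit:
    """Group-averaged fitted inter-quantile spreads for one covariate column."""

    iqr_case_mean: float
    iqr_control_mean: float
    n_case: int
    n_control: int

    def __post_init__(self):
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both groups must be non-empty")


def _binary_column(Xcol) -> np.ndarray:
    x = np.asarray(Xcol, dtype=float).ravel()
    vals = np.unique(x)
    if not np.all(np.isin(vals, (0.0, 1.0))) or vals.size != 2:
        raise ValueError("dispersion testing requires a binary 0/1 covariate with both classes present")
    return x


def fit_quantile_pair(Y, Xcol, Zaug, spec: DispersionSpec = DispersionSpec()) -> GroupedQuantileFit:
    """Fit the two quantile regressions of Y on [Xcol, Zaug] and average
    the fitted conditional spreads within each group.

    The per-subject spread is yhat_qhigh,i - yhat_qlow,i, equivalently
    r_i^{qlow} - r_i^{qhigh}.
    """
    Y = np.asarray(Y, dtype=float)
    x = _binary_column(Xcol)
    Zaug = np.asarray(Zaug, dtype=float)
    design = np.concatenate([x[:, None], Zaug], axis=1)
    r_low, _ = _linalg.quantile_fit(design, Y, spec.q_low, spec.tol, spec.max_iter)
    r_high, _ = _linalg.quantile_fit(design, Y, spec.q_high, spec.tol, spec.max_iter)
    spread = r_low - r_high  # = yhat_high - yhat_low
    case = x == 1.0
    fit = GroupedQuantileFit(
        iqr_case_mean=float(spread[case].mean()),
        iqr_control_mean=float(spread[~case].mean()),
        n_case=int(case.sum()),
        n_control=int((~case).sum()),
    )
    thr = _spread_floor(Y)
    if fit.iqr_case_mean <= thr or fit.iqr_control_mean <= thr:
        raise DegenerateDispersionError(
            "group-mean fitted spread is not meaningfully positive "
            f"(case={fit.iqr_case_mean:.3g}, control={fit.iqr_control_mean:.3g}); "
            "the conditional inter-quantile range is numerically degenerate"
        )
    return fit


def _spread_floor(Y) -> float:
    """Fitted spreads below this are indistinguishable from an exact fit."""
    return 1e-10 * max(float(np.std(Y)), 1e-300)


def dispersion_omega(fit: GroupedQuantileFit, two_sided: bool = False) -> float:
    """Evaluation score -log(mean case spread / mean control spread)."""
    if fit.iqr_case_mean <= 0 or fit.iqr_control_mean <= 0:
        raise DegenerateDispersionError("group-mean spreads must be strictly positive")
    ratio = np.log(fit.iqr_case_mean / fit.iqr_control_mean)
    return float(-abs(ratio)) if two_sided else float(-ratio)


def run_dispersion_test(problem: RegressionProblem, perms: PermutationSet,
                        spec: DispersionSpec = DispersionSpec(),
                        alpha: float = 0.05, two_sided: bool = False) -> TestResult:
    """Paired-permutation test for a case/control difference in conditional
    inter-quantile range.

    For each permutation pi, four quantile regressions are fitted (the
    original and permuted covariate, each at q_low and q_high) on the
    augmented design, and the grouped spread ratio scored; the original
    grouping uses X and the permuted grouping uses X_pi.
    """
    if problem.d != 1:
        raise ValueError("dispersion testing requires a single covariate column")
    if perms.n != problem.n:
        raise ValueError("permutation length does not match data")
    x = _binary_column(problem.X[:, 0])
    Y = problem.Y
    Zaug = _augment(problem.Z, perms.perms)  # (B, n, 2p)
    B = perms.B
    x_orig = np.broadcast_to(x, (B, problem.n))
    x_perm = x[perms.perms]
    basis_z = _linalg.span_basis(Zaug)
    omega_orig = _batched_omega(Y, x_orig, basis_z, spec, two_sided)
    omega_perm = _batched_omega(Y, x_perm, basis_z, spec, two_sided)
    pvalue = pvalue_from_scores(omega_orig, omega_perm)
    return TestResult(
        pvalue=pvalue, B=B, omega_orig=omega_orig, omega_perm=omega_perm,
        n_ties=int(np.count_nonzero(omega_orig == omega_perm)),
        alpha=float(alpha), seed=perms.seed,
    )


def _batched_omega(Y, xcols, basis_z, spec: DispersionSpec, two_sided: bool) -> np.ndarray:
    """Scores for a batch of binary covariate columns sharing Y and the
    augmented-control span basis."""
    basis = _linalg.extend_basis(basis_z, xcols[..., None])
    design = basis[0]  # the solver only needs shapes from the design
    r_low, _ = _linalg.quantile_fit(design, Y, spec.q_low, spec.tol, spec.max_iter,
                                    basis=basis)
    r_high, _ = _linalg.quantile_fit(design, Y, spec.q_high, spec.tol, spec.max_iter,
                                     basis=basis)
    spread = r_low - r_high  # (B, n)
    case = xcols == 1.0
    n_case = case.sum(axis=1)
    n_ctrl = (~case).sum(axis=1)
    case_mean = np.sum(spread * case, axis=1) / n_case
    ctrl_mean = np.sum(spread * ~case, axis=1) / n_ctrl
    thr = _spread_floor(Y)
    bad = (case_mean <= thr) | (ctrl_mean <= thr)
    if np.any(bad):
        b = int(np.argmax(bad))
        raise DegenerateDispersionError(
            f"nonpositive group-mean fitted spread in permutation pair b={b} "
            f"(case={case_mean[b]:.3g}, control={ctrl_mean[b]:.3g})"
        )
    ratio = np.log(case_mean / ctrl_mean)
    return -np.abs(ratio) if two_sided else -ratio
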