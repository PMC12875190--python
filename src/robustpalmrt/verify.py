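"""Empirical certification of the fitter contract.

The permutation p-value is valid only if the fitting algorithm is (1)
shift invariant over the span of the augmented controls and (2) invariant
under joint row permutation.  Both conditions are explicitly checkable,
and this module ships the checker so users can certify custom fitters
before trusting p-values built on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitters import get_fitter

__all__ = ["ConditionReport", "check_conditions"]


@dataclass(frozen=True)
class ConditionReport:
    """Worst-case deviations observed over the random draws."""

    shift_deviation: float
    permutation_deviation: float
    tol: float
    n_draws: int

    @property
    def passed(self) -> bool:
        return self.shift_deviation < self.tol and self.permutation_deviation < self.tol


def _summary_distance(a, b) -> float:
    return max(abs(a.scale - b.scale),
               float(np.max(np.abs(a.residuals_ordered - b.residuals_ordered))))


def check_conditions(fitter, n: int = 25, d: int = 1, p: int = 3,
                     n_draws: int = 20, tol: float = 1e-6, seed: int = 0) -> ConditionReport:
    """Check shift invariance and row symmetry on random instances.

    For each draw a random problem (standard-normal Y, X, Z with an
    intercept column in Z) and a random permutation pi are generated and
    the fit summary on (Y, X, [Z, Z_pi]) is compared against

    * the fit with Y shifted by [Z, Z_pi] gamma for random gamma, and
    * the fit with the rows of (Y, X, [Z, Z_pi]) jointly permuted by a
      random sigma.

    Returns the worst deviations; ``report.passed`` is True when both are
    below ``tol``.
    """
    fitter = get_fitter(fitter)
    rng = np.random.default_rng(seed)
    worst_shift = 0.0
    worst_perm = 0.0
    for _ in range(n_draws):
        Y = rng.standard_normal(n)
        X = rng.standard_normal((n, d))
        Z = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))]) if p > 1 \
            else np.ones((n, 1))
        pi = rng.permutation(n)
        Zaug = np.concatenate([Z, Z[pi]], axis=1)
        base = fitter.fit(Y, X, Zaug)

        gamma = rng.standard_normal(Zaug.shape[1])
        shifted = fitter.fit(Y + Zaug @ gamma, X, Zaug)
        worst_shift = max(worst_shift, _summary_distance(base, shifted))

        sigma = rng.permutation(n)
        permuted = fitter.fit(Y[sigma], X[sigma], Zaug[sigma])
        worst_perm = max(worst_perm, _summary_distance(base, permuted))
    return ConditionReport(shift_deviation=worst_shift, permutation_deviation=worst_perm,
                           tol=tol, n_draws=n_draws)
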