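"""Model-evaluation functions: map a fit summary to a score where smaller
means better fit.

Every score is a symmetric function of the residual vector, so the
composition of any shipped fitter and evaluator inherits the row-symmetry
required for a valid permutation p-value.  The scale-aware Huber score
consumes the fitter's estimated scale, which all shipped fitters derive
from the augmented controls alone -- both members of a comparison pair are
therefore scored on a common scale.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateScaleError
from .fitters import DEFAULT_DELTA, FitSummary, huber_rho


def l2_score(r):
    """Sum of squared residuals (monotone equivalent of the L2 norm)."""
    return np.sum(np.square(np.asarray(r, dtype=float)), axis=-1)


def l1_score(r):
    """Sum of absolute residuals."""
    return np.sum(np.abs(np.asarray(r, dtype=float)), axis=-1)


def scaled_huber_score(fit: FitSummary, delta: float = DEFAULT_DELTA):
    """Huber norm of the standardized residuals, sum_i rho(r_i / s)."""
    if fit.scale is None:
        raise DegenerateScaleError(
            "fit carries no scale estimate; the scaled Huber score needs one")
    if not fit.scale > 0:
        raise ValueError("scale must be positive")
    return float(np.sum(huber_rho(fit.residuals_ordered / fit.scale, delta)))


class L2Evaluator:
    name = "l2"
    needs_scale = False

    def __call__(self, fit: FitSummary) -> float:
        return float(l2_score(fit.residuals_ordered))

    def score(self, residuals, scale):
        """Vectorized scores for a batch of residual vectors (the scale is
        ignored by the L2 criterion)."""
        return l2_score(residuals)


class L1Evaluator:
    name = "l1"
    needs_scale = False

    def __call__(self, fit: FitSummary) -> float:
        return float(l1_score(fit.residuals_ordered))

    def score(self, residuals, scale):
        return l1_score(residuals)


class ScaledHuberEvaluator:
    """Huber loss of the scale-standardized residuals (the robust default)."""

    name = "huber"
    needs_scale = True

    def __init__(self, delta: float = DEFAULT_DELTA):
        if delta <= 0:
            raise ValueError("delta must be positive")
        self.delta = delta

    def __call__(self, fit: FitSummary) -> float:
        return scaled_huber_score(fit, self.delta)

    def score(self, residuals, scale):
        residuals = np.asarray(residuals, dtype=float)
        scale = np.asarray(scale, dtype=float)
        if not np.all(np.isfinite(scale) & (scale > 0)):
            raise DegenerateScaleError(
                "a permutation pair carries no positive scale estimate")
        z = residuals / scale[..., None]
        return np.sum(huber_rho(z, self.delta), axis=-1)


EVALUATORS = {
    "l1": L1Evaluator,
    "l2": L2Evaluator,
    "huber": ScaledHuberEvaluator,
}


def get_evaluator(name_or_evaluator, **kwargs):
    """Resolve an evaluator by registry name ("l1", "l2", "huber") or pass
    an evaluator object through unchanged."""
    if isinstance(name_or_evaluator, str):
        try:
            return EVALUATORS[name_or_evaluator](**kwargs)
        except KeyError:
            raise ValueError(
                f"unknown evaluator {name_or_evaluator!r}; available: {sorted(EVALUATORS)}"
            ) from None
    return name_or_evaluator
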