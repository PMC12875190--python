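"""Model-fitting algorithms for the paired-permutation framework.

A fitter maps ``(Y, X, Zaug)`` -- response, covariate of interest and the
*augmented* control matrix ``[Z, Z_pi]`` -- to a :class:`FitSummary`
consisting of an estimated residual scale and the order statistics of the
residuals.  Every shipped fitter satisfies the two conditions that make the
permutation p-value valid:

* shift invariance -- the summary is unchanged when Y is shifted by any
  vector in the column span of the augmented controls, and
* row symmetry -- the summary is unchanged under a joint permutation of the
  rows of (Y, X, Zaug).

Row symmetry is enforced mechanically by sorting the residuals; shift
invariance holds because every iteration of every solver depends on Y only
through span-determined least-squares projections.  Both conditions can be
certified empirically for custom fitters with :mod:`robustpalmrt.verify`.

The scale estimate of each fitter is computed from a *preliminary* fit of Y
on the augmented controls alone.  It therefore never depends on X or its
permuted copy, so the two members of a comparison pair share one scale and
their evaluation scores are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _linalg
from .exceptions import DegenerateScaleError

#: Huber corner giving 95% efficiency at the normal model.
DEFAULT_DELTA = 1.345

#: Multiplier making the MAD a consistent estimate of the standard
#: deviation at the normal model (1/Phi^{-1}(3/4)).
MAD_NORMAL_CONSTANT = 1.4826


@dataclass(frozen=True)
class HuberSpec:
    """Tuning constants for Huber M-estimation.

    delta is the corner of the Huber criterion in standardized-residual
    units; max_iter and tol control the IRLS stopping rule (maximum
    relative coefficient change).
    """

    delta: float = DEFAULT_DELTA
    max_iter: int = 50
    tol: float = 1e-6

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class FitSummary:
    """Output of a fitting algorithm: scale and ordered residuals.

    ``scale`` may be None when the fit does not carry a (finite, positive)
    scale estimate -- e.g. an OLS fit of a response lying exactly in the
    control span; scale-free evaluators still work, scale-aware ones
    refuse such a summary.
    """

    scale: float | None
    residuals_ordered: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.scale is not None and not self.scale > 0:
            raise ValueError("scale must be positive (or None)")
        r = np.asarray(self.residuals_ordered, dtype=float)
        if np.any(np.diff(r) < 0):
            raise ValueError("residuals_ordered must be nondecreasing")
        object.__setattr__(self, "residuals_ordered", r)


def ols_residuals(Y, design):
    """Residuals of Y from its orthogonal projection onto span(design).

    Rank-deficient designs are handled through the minimum-norm solution,
    so the result depends only on the column span.
    """
    Y = np.asarray(Y, dtype=float)
    design = np.asarray(design, dtype=float)
    return _linalg.ls_residuals(design, Y)


def mad(r, constant: float = MAD_NORMAL_CONSTANT) -> float:
    """Median absolute deviation from the median, times a consistency
    constant (1.4826 by default, for normal consistency; pass 1.0 for the
    raw MAD).

    Raises
    ------
    DegenerateScaleError
        If the raw MAD is exactly zero.
    """
    r = np.asarray(r, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two residuals")
    value = float(_linalg.raw_mad(r))
    if value <= 0:
        raise DegenerateScaleError("MAD is zero: residuals are constant on a majority", residuals=r)
    return constant * value


def huber_rho(t, delta: float = DEFAULT_DELTA):
    """Huber criterion: t^2/2 inside [-delta, delta], linear outside."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    t = np.abs(np.asarray(t, dtype=float))
    return np.where(t <= delta, 0.5 * t * t, delta * t - 0.5 * delta * delta)


def huber_irls_fixed_scale(Y, design, s: float, spec: HuberSpec = HuberSpec()):
    """Huber regression residuals with the scale frozen at ``s``.

    IRLS initialized at OLS; weights are 1 inside the corner and
    delta/|r/s| outside.  Non-convergence at max_iter emits a warning (the
    fit is still usable and the permutation test remains valid)."""
    if not s > 0:
        raise ValueError("scale must be positive")
    Y = np.asarray(Y, dtype=float)
    design = np.asarray(design, dtype=float)
    r, _, converged = _linalg.huber_irls(
        design, Y, spec.delta, scale=s, max_iter=spec.max_iter, tol=spec.tol
    )
    if not np.all(converged):
        warnings.warn("Huber IRLS did not converge within max_iter", RuntimeWarning)
    return r


def huber_fit_with_preliminary_scale(
    Y, X, Zaug, spec: HuberSpec = HuberSpec(), mad_constant: float = MAD_NORMAL_CONSTANT
) -> FitSummary:
    """The composite Huber fitter: preliminary scale, then fixed-scale fit.

    Step 1 runs a full robust regression of Y on the augmented controls
    alone, re-estimating the scale by (scaled) MAD of the current residuals
    at every IRLS iteration.  Step 2 freezes the scale at the MAD of the
    final preliminary residuals.  Step 3 refits Y on ``[X, Zaug]`` by
    fixed-scale Huber IRLS.  Because the scale comes from the preliminary
    regression it is identical for the original and permuted fit of one
    comparison pair.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float).T).T
    Zaug = np.asarray(Zaug, dtype=float)
    _, s, _ = _linalg.huber_irls(
        Zaug, Y, spec.delta, scale=None, mad_constant=mad_constant,
        max_iter=spec.max_iter, tol=spec.tol,
    )
    s = float(s)
    if s <= 0:
        raise DegenerateScaleError("preliminary fit produced a zero scale")
    full = np.concatenate([X, Zaug], axis=1)
    r = huber_irls_fixed_scale(Y, full, s, spec)
    return FitSummary(scale=s, residuals_ordered=np.sort(r))


def quantile_residuals(Y, design, q: float, tol: float = 1e-8, max_iter: int = 50):
    """Quantile-regression residuals at quantile q.

    The solver is a deterministic primal-dual interior-point method on the
    check-loss dual (the Frisch-Newton formulation standard in quantile
    regression software), so repeated calls on identical inputs agree
    bit-for-bit and the non-uniqueness of the minimizer is resolved by a
    fixed convention.
    """
    Y = np.asarray(Y, dtype=float)
    design = np.asarray(design, dtype=float)
    r, converged = _linalg.quantile_fit(design, Y, q, tol=tol, max_iter=max_iter)
    if not np.all(converged):
        warnings.warn(f"quantile solver (q={q}) did not close the duality gap "
                      "within max_iter", RuntimeWarning)
    return r


def _augment(Z, perms):
    """Stack of augmented control matrices [Z, Z_pi], shape (B, n, 2p)."""
    Z = np.asarray(Z, dtype=float)
    Zperm = Z[perms]  # (B, n, p)
    B = perms.shape[0]
    Zrep = np.broadcast_to(Z, (B,) + Z.shape)
    return np.concatenate([Zrep, Zperm], axis=2)


class HuberFitter:
    """Huber regression with preliminary-regression MAD scale (the default
    robust location fitter)."""

    name = "huber"

    def __init__(self, spec: HuberSpec = HuberSpec(), mad_constant: float = MAD_NORMAL_CONSTANT):
        self.spec = spec
        self.mad_constant = mad_constant

    def fit(self, Y, X, Zaug) -> FitSummary:
        return huber_fit_with_preliminary_scale(Y, X, Zaug, self.spec, self.mad_constant)

    def fit_pair_batch(self, Y, X, Z, perms):
        """Fit the (original, permuted) pair for every permutation at once.

        Returns ``(scales (B,), resid_orig (B, n), resid_perm (B, n))``;
        residuals are unsorted (evaluation scores are symmetric)."""
        Y = np.asarray(Y, dtype=float)
        X = np.asarray(X, dtype=float)
        Zaug = _augment(Z, perms)
        spec = self.spec
        basis_z = _linalg.span_basis(Zaug)
        _, s, _ = _linalg.huber_irls(
            Zaug, Y, spec.delta, scale=None, mad_constant=self.mad_constant,
            max_iter=spec.max_iter, tol=spec.tol, basis=basis_z,
        )
        B = perms.shape[0]
        Xrep = np.broadcast_to(X, (B,) + X.shape)
        r_orig, _, _ = _linalg.huber_irls(
            Zaug, Y, spec.delta, scale=s, max_iter=spec.max_iter, tol=spec.tol,
            basis=_linalg.extend_basis(basis_z, Xrep),
        )
        r_perm, _, _ = _linalg.huber_irls(
            Zaug, Y, spec.delta, scale=s, max_iter=spec.max_iter, tol=spec.tol,
            basis=_linalg.extend_basis(basis_z, X[perms]),
        )
        return s, r_orig, r_perm


class OLSFitter:
    """Ordinary least-squares projection residuals.

    The scale is the (scaled) MAD of the residuals of the preliminary OLS
    of Y on the augmented controls alone, so scale-aware evaluators can be
    combined with an OLS fit.
    """

    name = "ols"

    def __init__(self, mad_constant: float = MAD_NORMAL_CONSTANT):
        self.mad_constant = mad_constant

    def fit(self, Y, X, Zaug) -> FitSummary:
        Y = np.asarray(Y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float).T).T
        Zaug = np.asarray(Zaug, dtype=float)
        try:
            s = mad(ols_residuals(Y, Zaug), self.mad_constant)
            if s <= _linalg.SCALE_RTOL * max(np.max(np.abs(Y)), 1e-300):
                s = None
        except DegenerateScaleError:
            s = None  # scale-free evaluators can still proceed
        r = ols_residuals(Y, np.concatenate([X, Zaug], axis=1))
        return FitSummary(scale=s, residuals_ordered=np.sort(r))

    def fit_pair_batch(self, Y, X, Z, perms):
        Y = np.asarray(Y, dtype=float)
        X = np.asarray(X, dtype=float)
        Zaug = _augment(Z, perms)
        B = perms.shape[0]
        basis_z = _linalg.span_basis(Zaug)
        Yb = np.broadcast_to(Y, (B,) + Y.shape)
        fitted, _ = _linalg.basis_wls_fitted(*basis_z, Yb)
        s = self.mad_constant * _linalg.raw_mad(Y - fitted)
        # degenerate preliminary fits carry no scale; scale-aware
        # evaluators will refuse them downstream
        s = np.where(s > _linalg.SCALE_RTOL * max(np.max(np.abs(Y)), 1e-300), s, np.nan)
        Xrep = np.broadcast_to(X, (B,) + X.shape)
        U_o, dead_o = _linalg.extend_basis(basis_z, Xrep)
        U_p, dead_p = _linalg.extend_basis(basis_z, X[perms])
        r_orig = Y - _linalg.basis_wls_fitted(U_o, dead_o, Yb)[0]
        r_perm = Y - _linalg.basis_wls_fitted(U_p, dead_p, Yb)[0]
        return s, r_orig, r_perm


class QuantileFitter:
    """Quantile-regression residuals at a single quantile (default median).

    The scale is the (scaled) MAD of the preliminary quantile fit of Y on
    the augmented controls alone."""

    name = "quantile"

    def __init__(self, q: float = 0.5, mad_constant: float = MAD_NORMAL_CONSTANT,
                 tol: float = 1e-8, max_iter: int = 50):
        if not 0 < q < 1:
            raise ValueError("q must be strictly between 0 and 1")
        self.q = q
        self.mad_constant = mad_constant
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, Y, X, Zaug) -> FitSummary:
        Y = np.asarray(Y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float).T).T
        Zaug = np.asarray(Zaug, dtype=float)
        s = mad(quantile_residuals(Y, Zaug, self.q, self.tol, self.max_iter),
                self.mad_constant)
        if s <= _linalg.SCALE_RTOL * max(np.max(np.abs(Y)), 1e-300):
            raise DegenerateScaleError("preliminary quantile-fit scale is (numerically) zero")
        r = quantile_residuals(Y, np.concatenate([X, Zaug], axis=1), self.q,
                               self.tol, self.max_iter)
        return FitSummary(scale=s, residuals_ordered=np.sort(r))

    def fit_pair_batch(self, Y, X, Z, perms):
        Y = np.asarray(Y, dtype=float)
        X = np.asarray(X, dtype=float)
        Zaug = _augment(Z, perms)
        basis_z = _linalg.span_basis(Zaug)
        r_prelim, _ = _linalg.quantile_fit(Zaug, Y, self.q, self.tol, self.max_iter,
                                           basis=basis_z)
        s = self.mad_constant * _linalg.raw_mad(r_prelim)
        if np.any(s <= _linalg.SCALE_RTOL * max(np.max(np.abs(Y)), 1e-300)):
            raise DegenerateScaleError("preliminary quantile-fit scale is (numerically) zero")
        B = perms.shape[0]
        Xrep = np.broadcast_to(X, (B,) + X.shape)
        r_orig, _ = _linalg.quantile_fit(
            Zaug, Y, self.q, self.tol, self.max_iter,
            basis=_linalg.extend_basis(basis_z, Xrep))
        r_perm, _ = _linalg.quantile_fit(
            Zaug, Y, self.q, self.tol, self.max_iter,
            basis=_linalg.extend_basis(basis_z, X[perms]))
        return s, r_orig, r_perm


FITTERS = {
    "ols": OLSFitter,
    "huber": HuberFitter,
    "quantile": QuantileFitter,
}


def get_fitter(name_or_fitter, **kwargs):
    """Resolve a fitter by registry name ("ols", "huber", "quantile") or
    pass a fitter object through unchanged."""
    if isinstance(name_or_fitter, str):
        try:
            return FITTERS[name_or_fitter](**kwargs)
        except KeyError:
            raise ValueError(
                f"unknown fitter {name_or_fitter!r}; available: {sorted(FITTERS)}"
            ) from None
    return name_or_fitter
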