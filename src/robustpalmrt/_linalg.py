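"""Batched linear-algebra kernels.

All solvers accept design matrices with an optional leading batch axis,
``(..., n, k)``, so that the B augmented designs of one permutation test
can be processed with a handful of BLAS calls instead of a Python loop
over permutations.

Every least-squares subproblem is solved on an orthonormal basis of the
design's column span (computed once per fit by SVD with a relative
singular-value cutoff).  Augmented control matrices ``[Z, Z_pi]`` are rank
deficient whenever Z contains a constant column -- the permuted copy of a
constant column is the column itself -- and working on the span makes
every fit depend only on the column *span* of the design, which is
exactly what shift invariance over the controls requires.
"""

from __future__ import annotations

import numpy as np

#: Relative singular-value cutoff used when extracting a span basis.
BASIS_RCOND = 1e-9


def span_basis(design: np.ndarray, rcond: float = BASIS_RCOND):
    """Orthonormal bases for the column spans of a stack of matrices.

    Returns ``(U, dead)`` where ``U`` has shape ``(..., n, k)`` with the
    columns beyond each matrix's numerical rank zeroed out, and ``dead``
    is the boolean ``(..., k)`` mask of those zeroed columns.  Zeroing
    (rather than slicing) keeps the batch rectangular when ranks differ
    across the batch.
    """
    u, s, _ = np.linalg.svd(design, full_matrices=False)
    smax = s[..., :1]
    alive = s > rcond * np.where(smax > 0, smax, 1.0)
    return u * alive[..., None, :], ~alive


def extend_basis(basis, cols: np.ndarray, rcond: float = BASIS_RCOND):
    """Extend an orthonormal span basis with additional design columns.

    ``cols`` has shape ``(..., n, d)``; each column is orthogonalized
    against the current basis (two Gram-Schmidt passes) and appended, or
    marked dead when it lies in the span already.  Returns ``(U, dead)``
    for the enlarged span.
    """
    U, dead = basis
    cols = np.asarray(cols, dtype=float)
    batch = np.broadcast_shapes(U.shape[:-2], cols.shape[:-2])
    n, k = U.shape[-2], U.shape[-1]
    d = cols.shape[-1]
    Ucur = np.zeros(batch + (n, k + d))
    Ucur[..., :k] = U
    deadcur = np.zeros(batch + (k + d,), dtype=bool)
    deadcur[..., :k] = dead
    for j in range(d):
        col = np.broadcast_to(cols[..., j], batch + (n,))
        v = col.copy()
        for _ in range(2):
            proj = (np.swapaxes(Ucur, -1, -2) @ v[..., None])[..., 0]
            v = v - (Ucur @ proj[..., None])[..., 0]
        nrm = np.linalg.norm(v, axis=-1)
        colnrm = np.linalg.norm(col, axis=-1)
        alive = nrm > rcond * np.where(colnrm > 0, colnrm, 1.0)
        unit = v / np.where(nrm > 0, nrm, 1.0)[..., None]
        Ucur[..., k + j] = unit * alive[..., None]
        deadcur[..., k + j] = ~alive
    return Ucur, deadcur


def basis_wls_fitted(U: np.ndarray, dead: np.ndarray, y: np.ndarray,
                     w: np.ndarray | None = None):
    """Weighted least-squares fitted values on an orthonormal span basis.

    ``U, dead`` come from :func:`span_basis`.  Dead columns are excluded
    by giving them a unit diagonal and zero right-hand side.  Returns
    ``(fitted, coef)``.
    """
    ut = np.swapaxes(U, -1, -2)
    if w is None:
        g = ut @ U
        c = (ut @ y[..., None])[..., 0]
    else:
        uw = ut * w[..., None, :]
        g = uw @ U
        c = (uw @ y[..., None])[..., 0]
    k = U.shape[-1]
    g = g + dead[..., None] * np.eye(k)
    try:
        coef = np.linalg.solve(g, c[..., None])[..., 0]
    except np.linalg.LinAlgError:  # design columns beyond the basis collapsed
        coef = (np.linalg.pinv(g) @ c[..., None])[..., 0]
    return (U @ coef[..., None])[..., 0], coef


def wls_coef(design: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Minimum-norm weighted least-squares coefficients (pseudo-inverse of
    the normal equations; generic non-batched workhorse)."""
    dt = np.swapaxes(design, -1, -2)
    if w is None:
        g = dt @ design
        c = (dt @ y[..., None])[..., 0]
    else:
        dw = dt * w[..., None, :]
        g = dw @ design
        c = (dw @ y[..., None])[..., 0]
    ginv = np.linalg.pinv(g, rcond=1e-12, hermitian=True)
    return (ginv @ c[..., None])[..., 0]


def ls_residuals(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residuals of the orthogonal projection of y onto span(design)."""
    U, dead = span_basis(design)
    fitted, _ = basis_wls_fitted(U, dead, np.broadcast_to(y, design.shape[:-2] + y.shape[-1:]))
    return y - fitted


def raw_mad(r: np.ndarray) -> np.ndarray:
    """Median absolute deviation from the median along the last axis (no
    consistency constant)."""
    med = np.median(r, axis=-1, keepdims=True)
    return np.median(np.abs(r - med), axis=-1)


def huber_weights(r: np.ndarray, scale, delta: float) -> np.ndarray:
    """IRLS case weights for the Huber criterion at standardized residuals
    r/scale: 1 inside the corner, delta/|r/scale| outside."""
    z = np.abs(r) / np.asarray(scale)[..., None]
    with np.errstate(divide="ignore"):
        w = np.where(z <= delta, 1.0, delta / np.where(z > 0, z, 1.0))
    return w


def _rel_change(beta: np.ndarray, beta0: np.ndarray) -> np.ndarray:
    denom = np.maximum(np.max(np.abs(beta0), axis=-1), 1e-12)
    return np.max(np.abs(beta - beta0), axis=-1) / denom


def _as_batched(design, y):
    """Broadcast design/response to a common leading batch shape."""
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    squeeze = design.ndim == 2 and y.ndim == 1
    if design.ndim == 2:
        design = design[None]
    batch = np.broadcast_shapes(design.shape[:-2], y.shape[:-1])
    n = design.shape[-2]
    design = np.broadcast_to(design, batch + design.shape[-2:])
    y = np.broadcast_to(y, batch + (n,))
    return design, y, squeeze


def huber_irls(
    design: np.ndarray,
    y: np.ndarray,
    delta: float,
    scale: np.ndarray | float | None = None,
    mad_constant: float = 1.4826,
    max_iter: int = 50,
    tol: float = 1e-6,
    basis=None,
):
    """Huber IRLS, optionally re-estimating the scale by MAD each iteration.

    With ``scale`` given, the scale is frozen (the fixed-scale refit of
    the composite fitter).  With ``scale=None`` the scale is re-estimated
    as ``mad_constant * MAD`` of the current residuals every iteration
    (MASS-style concurrent estimation), starting from the OLS residuals.
    Converged batch elements drop out of the iteration.

    Returns ``(residuals, scale, converged)`` where ``scale`` is the
    frozen scale or the MAD of the final residuals when re-estimating.
    """
    design, y, squeeze = _as_batched(design, y)
    if basis is None:
        basis = span_basis(design)
    U, dead = basis
    yref = np.max(np.abs(y), axis=-1)  # pre-projection magnitude
    # project the response off the design span: a no-op for the residuals
    # that makes shift invariance over the span exact in floating point
    y = y - (U @ (np.swapaxes(U, -1, -2) @ y[..., None]))[..., 0]
    fitted, beta = basis_wls_fitted(U, dead, y)  # OLS initialization
    r = y - fitted
    batch = r.shape[:-1]
    fixed = scale is not None
    if fixed:
        s = np.broadcast_to(np.asarray(scale, dtype=float), batch).astype(float).copy()
    else:
        s = mad_constant * raw_mad(r)
        _check_scale(s, r, yref)
    converged = np.zeros(batch, dtype=bool)
    flat = lambda a: a.reshape((-1,) + a.shape[len(batch):])
    Uf, deadf, yf, rf, sf, betaf = map(flat, (U, dead, y, r, s, beta))
    convf = converged.reshape(-1)
    active = np.arange(convf.size)
    for _ in range(max_iter):
        Ua, da, ya, ra, sa = Uf[active], deadf[active], yf[active], rf[active], sf[active]
        if not fixed:
            sa = mad_constant * raw_mad(ra)
            _check_scale(sa, ra, yref.reshape(-1)[active])
            sf[active] = sa
        w = huber_weights(ra, sa, delta)
        fitted_a, beta_a = basis_wls_fitted(Ua, da, ya, w)
        ra = ya - fitted_a
        rf[active] = ra
        done = _rel_change(beta_a, betaf[active]) < tol
        betaf[active] = beta_a
        convf[active] = done
        active = active[~done]
        if active.size == 0:
            break
    if not fixed:
        sf = mad_constant * raw_mad(rf)
    r = rf.reshape(batch + r.shape[-1:])
    s = sf.reshape(batch)
    converged = convf.reshape(batch)
    if squeeze:
        return r[0], s[0], converged[0]
    return r, s, converged


#: A residual scale below this fraction of the response magnitude is
#: numerically indistinguishable from zero (the response lies in the span).
SCALE_RTOL = 1e-10


def _check_scale(s, r, yref):
    if np.any(s <= SCALE_RTOL * np.maximum(np.asarray(yref), 1e-300)):
        from .exceptions import DegenerateScaleError

        raise DegenerateScaleError(
            "MAD of preliminary residuals is (numerically) zero; the "
            "response lies in the span of the controls",
            residuals=r,
        )


def quantile_fit(
    design: np.ndarray,
    y: np.ndarray,
    q: float,
    tol: float = 1e-8,
    max_iter: int = 50,
    basis=None,
):
    """Quantile-regression residuals by a primal-dual interior-point method.

    Solves the dual linear program of the check-loss problem,

        max  y'd   s.t.  U'd = (1-q) U'1,   0 <= d <= 1,

    on an orthonormal span basis U of the design, with Mehrotra
    predictor-corrector steps; the equality multipliers are the primal
    coefficients (the Frisch-Newton formulation standard in quantile
    regression software).  The response is first projected onto the
    orthogonal complement of span(design) -- a mathematical no-op for the
    residuals that makes shift invariance over the design span exact in
    floating point.  The deterministic iteration also serves as the
    tie-breaking convention when the minimizer is not unique.

    Returns ``(residuals, converged)``; elements whose duality gap has not
    closed within ``max_iter`` are flagged unconverged but still carry the
    last iterate's residuals.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must be strictly between 0 and 1, got {q}")
    design, y, squeeze = _as_batched(design, y)
    if basis is None:
        basis = span_basis(design)
    U, dead = basis
    batch = y.shape[:-1]
    n = y.shape[-1]
    U = np.broadcast_to(U, batch + U.shape[-2:])
    dead = np.broadcast_to(dead, batch + dead.shape[-1:])
    k = U.shape[-1]
    Uf = np.ascontiguousarray(U).reshape(-1, n, k)
    deadf = np.ascontiguousarray(dead).reshape(-1, k)
    yf = np.ascontiguousarray(y).reshape(-1, n)
    m = yf.shape[0]
    At = Uf  # (m, n, k);  A = U^T
    A = np.swapaxes(Uf, -1, -2)  # (m, k, n)
    # project the response off the design span
    yf = yf - (Uf @ (A @ yf[..., None]))[..., 0]
    b = (1.0 - q) * np.sum(Uf, axis=1)  # A @ 1
    d = np.full((m, n), 1.0 - q)
    s = np.full((m, n), q)
    lam = np.zeros((m, k))
    z = np.maximum(-yf, 0.0) + 1.0
    w = yf + z
    rfin = yf.copy()
    convf = np.zeros(m, dtype=bool)
    active = np.arange(m)
    eye = np.eye(k)
    yscale = 1.0 + np.max(np.abs(yf), axis=-1)
    for _ in range(max_iter):
        Aa, Ata, ya, ba = A[active], At[active], yf[active], b[active]
        da, sa, za, wa, lama = d[active], s[active], z[active], w[active], lam[active]
        deada = deadf[active]
        gap = np.einsum("ij,ij->i", da, za) + np.einsum("ij,ij->i", sa, wa)
        r_d = ya - (Ata @ lama[..., None])[..., 0] - wa + za
        r_p = ba - (Aa @ da[..., None])[..., 0]
        obj = np.abs(np.einsum("ij,ij->i", ya, da))
        done = (
            (gap < tol * (1.0 + obj))
            & (np.max(np.abs(r_p), axis=-1) < tol)
            & (np.max(np.abs(r_d), axis=-1) < tol * yscale[active])
        )
        rfin[active] = ya - (Ata @ lama[..., None])[..., 0]
        convf[active[done]] = True
        keep = ~done
        active = active[keep]
        if active.size == 0:
            break
        Aa, Ata, ya, ba = Aa[keep], Ata[keep], ya[keep], ba[keep]
        da, sa, za, wa, lama = da[keep], sa[keep], za[keep], wa[keep], lama[keep]
        deada, r_d, r_p, gap = deada[keep], r_d[keep], r_p[keep], gap[keep]
        mu = gap / (2.0 * n)
        Q = 1.0 / (wa / sa + za / da)
        AQ = Aa * Q[..., None, :]
        M = AQ @ Ata + deada[..., None] * eye

        def newton(rc1, rc2):
            rhs_d = r_d - rc2 / sa + rc1 / da
            rhs = (AQ @ rhs_d[..., None])[..., 0] - r_p
            dlam = np.linalg.solve(M, rhs[..., None])[..., 0]
            dd = Q * (rhs_d - (Ata @ dlam[..., None])[..., 0])
            ds = -dd
            dz = (rc1 - za * dd) / da
            dw = (rc2 - wa * ds) / sa
            return dlam, dd, ds, dz, dw

        def steplen(dd, ds, dz, dw, tau=0.9995):
            with np.errstate(divide="ignore", invalid="ignore"):
                ap = np.minimum(
                    np.min(np.where(dd < 0, -da / dd, np.inf), axis=-1),
                    np.min(np.where(ds < 0, -sa / ds, np.inf), axis=-1),
                )
                ad = np.minimum(
                    np.min(np.where(dz < 0, -za / dz, np.inf), axis=-1),
                    np.min(np.where(dw < 0, -wa / dw, np.inf), axis=-1),
                )
            return np.minimum(tau * ap, 1.0), np.minimum(tau * ad, 1.0)

        # predictor (affine scaling)
        dlam, dd, ds, dz, dw = newton(-da * za, -sa * wa)
        ap, ad = steplen(dd, ds, dz, dw)
        gap_aff = (
            np.einsum("ij,ij->i", da + ap[:, None] * dd, za + ad[:, None] * dz)
            + np.einsum("ij,ij->i", sa + ap[:, None] * ds, wa + ad[:, None] * dw)
        )
        sigma = np.clip((gap_aff / gap) ** 3, 0.0, 1.0)
        mu_t = (sigma * mu)[:, None]
        # corrector
        dlam, dd2, ds2, dz2, dw2 = newton(mu_t - da * za - dd * dz, mu_t - sa * wa - ds * dw)
        ap, ad = steplen(dd2, ds2, dz2, dw2)
        da = da + ap[:, None] * dd2
        sa = sa + ap[:, None] * ds2
        lama = lama + ad[:, None] * dlam
        za = za + ad[:, None] * dz2
        wa = wa + ad[:, None] * dw2
        bad = ~(
            np.all(np.isfinite(da) & (da > 0), axis=-1)
            & np.all(np.isfinite(sa) & (sa > 0), axis=-1)
            & np.all(np.isfinite(za) & (za > 0), axis=-1)
            & np.all(np.isfinite(wa) & (wa > 0), axis=-1)
            & np.all(np.isfinite(lama), axis=-1)
        )
        if np.any(bad):
            # freeze numerically stalled elements at their last good iterate
            good = ~bad
            d[active[good]], s[active[good]] = da[good], sa[good]
            lam[active[good]], z[active[good]], w[active[good]] = (
                lama[good], za[good], wa[good],
            )
            active = active[good]
            if active.size == 0:
                break
        else:
            d[active], s[active] = da, sa
            lam[active], z[active], w[active] = lama, za, wa
    if active.size > 0:
        rfin[active] = yf[active] - (At[active] @ lam[active][..., None])[..., 0]
    r = rfin.reshape(batch + (n,))
    converged = convf.reshape(batch)
    if squeeze:
        return r[0], converged[0]
    return r, converged


def check_loss(r: np.ndarray, q: float) -> np.ndarray:
    """Total check (pinball) loss of a residual vector along the last axis."""
    return np.sum(np.where(r >= 0, q * r, (q - 1.0) * r), axis=-1)
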