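"""Gaussian linear mixed model with a single random intercept.

The marginal covariance of a group of ``m`` observations is
``sigma^2 I + tau^2 J`` (``J`` the all-ones matrix). Fitting profiles the
fixed effects and the residual variance analytically and optimizes the
variance ratio ``lambda = tau^2 / sigma^2`` in one dimension, so the fit is
exact up to scalar optimization tolerance. ML is used whenever the model
feeds a likelihood-ratio test on fixed effects; REML is available for final
reporting and for variance-function comparisons.

An optional variance function (one residual standard deviation per stratum
of a grouping column, the varIdent idiom) is fitted by direct optimization
of the exact marginal likelihood via rank-one (Sherman-Morrison) updates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import norm

from .formula import ModelSpec, build_design, check_full_rank, complete_cases
from .results import FittedModel

__all__ = ["fit_lmm"]

_LOG2PI = np.log(2.0 * np.pi)


def _group_structs(groups: pd.Series) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(groups, sort=True)
    return codes, len(uniques)


def _profiled_parts(lam: float, X, y, codes, n_groups):
    """A = X'V*^-1 X, b = X'V*^-1 y, q = y'V*^-1 y and logdet(V*) for
    V* = I + lam * J per group (V scaled by 1/sigma^2)."""
    m = np.bincount(codes, minlength=n_groups).astype(float)
    if lam == 0.0:
        A = X.T @ X
        b = X.T @ y
        q = float(y @ y)
        return A, b, q, 0.0
    c = lam / (1.0 + m * lam)                      # per-group shrinkage
    p = X.shape[1]
    Sx = np.zeros((n_groups, p))
    for j in range(p):
        Sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=n_groups)
    Sy = np.bincount(codes, weights=y, minlength=n_groups)
    A = X.T @ X - (Sx * c[:, None]).T @ Sx
    b = X.T @ y - Sx.T @ (c * Sy)
    q = float(y @ y - c @ (Sy * Sy))
    logdet = float(np.log1p(m * lam).sum())
    return A, b, q, logdet


def _profile_loglik(lam, X, y, codes, n_groups, reml):
    n, p = X.shape
    A, b, q, logdet = _profiled_parts(lam, X, y, codes, n_groups)
    beta = np.linalg.solve(A, b)
    rss = max(q - float(beta @ b), 1e-300)
    if reml:
        sigma2 = rss / (n - p)
        sign, logdetA = np.linalg.slogdet(A)
        ll = -0.5 * ((n - p) * (_LOG2PI + np.log(sigma2)) + logdet + logdetA + (n - p))
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * (_LOG2PI + np.log(sigma2)) + logdet + n)
    return ll, beta, sigma2, A


def _fit_homoscedastic(X, y, codes, n_groups, reml):
    def negll(phi):
        return -_profile_loglik(np.exp(phi), X, y, codes, n_groups, reml)[0]

    res = minimize_scalar(negll, bounds=(-25.0, 15.0), method="bounded",
                          options={"xatol": 1e-10})
    ll0 = _profile_loglik(0.0, X, y, codes, n_groups, reml)[0]
    if -res.fun >= ll0:
        lam = float(np.exp(res.x))
        boundary = res.x < -12.0
    else:
        lam, boundary = 0.0, True
    ll, beta, sigma2, A = _profile_loglik(lam, X, y, codes, n_groups, reml)
    cov = sigma2 * np.linalg.inv(A)
    return lam, beta, sigma2, ll, cov, boundary


def _hetero_parts(log_sds, log_tau, X, y, codes, n_groups, strata_codes):
    """Exact GLS pieces for V_g = D_g + tau^2 J via Sherman-Morrison."""
    sd = np.exp(log_sds)[strata_codes]
    dinv = 1.0 / (sd * sd)
    tau2 = np.exp(2.0 * log_tau)
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    q = 0.0
    logdet = 0.0
    order = np.argsort(codes, kind="stable")
    Xs, ys, ds = X[order], y[order], dinv[order]
    bounds = np.searchsorted(codes[order], np.arange(n_groups + 1))
    for g in range(n_groups):
        lo, hi = bounds[g], bounds[g + 1]
        if lo == hi:
            continue
        Xg, yg, dg = Xs[lo:hi], ys[lo:hi], ds[lo:hi]
        denom = 1.0 + tau2 * dg.sum()
        wX = Xg * dg[:, None]
        wy = yg * dg
        sx = wX.sum(axis=0)
        sy = wy.sum()
        A += Xg.T @ wX - (tau2 / denom) * np.outer(sx, sx)
        b += Xg.T @ wy - (tau2 / denom) * sx * sy
        q += float(yg @ wy) - (tau2 / denom) * sy * sy
        logdet += -float(np.log(dg).sum()) + np.log(denom)
    return A, b, q, logdet


def _hetero_loglik(params, X, y, codes, n_groups, strata_codes, n_strata, reml):
    log_sds, log_tau = params[:n_strata], params[n_strata]
    n, p = X.shape
    A, b, q, logdet = _hetero_parts(log_sds, log_tau, X, y, codes, n_groups,
                                    strata_codes)
    beta = np.linalg.solve(A, b)
    rss = q - float(beta @ b)
    if reml:
        _, logdetA = np.linalg.slogdet(A)
        ll = -0.5 * ((n - p) * _LOG2PI + logdet + logdetA + rss)
    else:
        ll = -0.5 * (n * _LOG2PI + logdet + rss)
    return ll, beta, A


def fit_lmm(spec: ModelSpec, data: pd.DataFrame,
            rows: pd.Index | None = None) -> FittedModel:
    """Fit a Gaussian LMM with one random intercept per level of ``spec.group``.

    ``rows`` restricts the fit to a fixed row set (used by the selection
    protocol so every nested fit sees identical observations); by default
    the complete cases for the spec's columns are used. Raises
    ``numpy.linalg.LinAlgError`` naming aliased terms for singular designs.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm requires a gaussian family spec")
    if rows is None:
        rows = complete_cases(data, spec)
    df = data.loc[rows]
    if len(df) == 0:
        raise ValueError("no complete-case rows for this model")
    X, names = build_design(df, spec)
    check_full_rank(X, names)
    y = np.asarray(df[spec.response], dtype=float)
    codes, n_groups = _group_structs(df[spec.group])
    reml = spec.estimation == "REML"
    n, p = X.shape

    if spec.variance_strata is None:
        lam, beta, sigma2, ll, cov, boundary = _fit_homoscedastic(
            X, y, codes, n_groups, reml)
        sigma = float(np.sqrt(sigma2))
        tau = float(np.sqrt(lam * sigma2))
        residual_sd: float | dict = sigma
        converged = True
        # BLUPs: u_g = lam * sum(resid_g) / (1 + m_g * lam)
        r = y - X @ beta
        m = np.bincount(codes, minlength=n_groups).astype(float)
        Rg = np.bincount(codes, weights=r, minlength=n_groups)
        u = lam * Rg / (1.0 + m * lam)
    else:
        strata_codes, strata = pd.factorize(df[spec.variance_strata], sort=True)
        n_strata = len(strata)
        if n_strata < 2:
            raise ValueError("variance_strata column has fewer than 2 levels")
        # start from the homoscedastic fit
        lam0, beta0, s2, _, _, _ = _fit_homoscedastic(X, y, codes, n_groups, reml)
        x0 = np.concatenate([np.full(n_strata, 0.5 * np.log(s2)),
                             [0.5 * np.log(max(lam0 * s2, 1e-8 * s2))]])

        def negll(params):
            try:
                return -_hetero_loglik(params, X, y, codes, n_groups,
                                       strata_codes, n_strata, reml)[0]
            except np.linalg.LinAlgError:
                return 1e12

        opt = minimize(negll, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-10})
        converged = bool(opt.success)
        if not converged:
            warnings.warn("variance-function LMM did not converge", RuntimeWarning)
        ll, beta, A = _hetero_loglik(opt.x, X, y, codes, n_groups,
                                     strata_codes, n_strata, reml)
        cov = np.linalg.inv(A)
        sds = np.exp(opt.x[:n_strata])
        tau = float(np.exp(opt.x[n_strata]))
        boundary = tau < 1e-4 * sds.mean()
        residual_sd = {str(s): float(v) for s, v in zip(strata, sds)}
        # approximate BLUPs with the stratum-averaged shrinkage
        r = y - X @ beta
        dinv = 1.0 / (sds[strata_codes] ** 2)
        num = np.bincount(codes, weights=r * dinv, minlength=n_groups)
        den = np.bincount(codes, weights=dinv, minlength=n_groups)
        u = tau ** 2 * num / (1.0 + tau ** 2 * den)

    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * norm.sf(np.abs(tvals))
    fitted = X @ beta + u[codes]
    residuals = y - fitted
    group_levels = pd.factorize(df[spec.group], sort=True)[1]
    return FittedModel(
        spec=spec,
        coefficients=dict(zip(names, beta.astype(float))),
        std_errors=dict(zip(names, se.astype(float))),
        t_or_z=dict(zip(names, tvals.astype(float))),
        p_values=dict(zip(names, pvals.astype(float))),
        random_sd=float(tau),
        residual_sd=residual_sd,
        loglik=float(ll),
        n_obs=n,
        n_groups=n_groups,
        converged=converged,
        estimation=spec.estimation,
        boundary=bool(boundary),
        row_index=rows,
        group_effects=dict(zip(group_levels, u.astype(float))),
        fitted=fitted,
        residuals=residuals,
    )
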