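"""Numerical core for nested random-intercept mixed models.

Gaussian models are fitted by REML (or ML) with the fixed effects and the
residual variance profiled out, leaving only the variance ratios
``theta_l = sigma_l^2 / sigma_e^2`` to the optimizer.  All linear algebra
runs in the q-dimensional random-effect space via the Woodbury identity
(q = total number of groups), so repeated fits on simulation replicates
stay cheap.

Binomial (logit) models use the Laplace approximation to the marginal
likelihood, with an inner Newton solve for the random-effect modes and an
outer quasi-Newton optimization over fixed effects and log random-effect
SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy.linalg import solve_triangular

CONV_TOL = 1e-8
MAX_ITER = 200
_LOG_RATIO_BOUNDS = (-8.0, 4.0)  # bounds on log(sigma_l / sigma_e)


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a binomial model."""


@dataclass
class RandomDesign:
    """Stacked indicator design for nested random intercepts."""

    z: np.ndarray          # (n, q) indicator matrix
    col_level: np.ndarray  # (q,) level index of each column
    n_levels: int
    groups_per_level: list[int]

    @classmethod
    def from_labels(cls, label_arrays, n=None):
        """Build from per-level composite group labels (outermost first)."""
        blocks = []
        col_level = []
        groups_per_level = []
        if n is None:
            n = len(label_arrays[0]) if label_arrays else 0
        for lvl, labels in enumerate(label_arrays):
            codes, uniques = np.unique(np.asarray(labels), return_inverse=True)
            q_l = len(codes)
            block = np.zeros((n, q_l))
            block[np.arange(n), uniques] = 1.0
            blocks.append(block)
            col_level.extend([lvl] * q_l)
            groups_per_level.append(q_l)
        z = np.hstack(blocks) if blocks else np.zeros((n, 0))
        return cls(z, np.asarray(col_level, dtype=int), len(label_arrays), groups_per_level)

    @property
    def q(self):
        return self.z.shape[1]


@dataclass
class GaussianFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_resid: float
    sigma_levels: np.ndarray       # per-level random-intercept SDs
    sigma_se_log: np.ndarray       # asymptotic SE of log sigma per level
    boundary: np.ndarray           # per-level boundary flags
    loglik: float                  # restricted (REML) or full (ML) loglik
    reml: bool
    blup: np.ndarray
    fitted_marginal: np.ndarray
    fitted_conditional: np.ndarray
    converged: bool


def _gaussian_pieces(xtx, xty, yty, ztx, zty, ztz, theta_col):
    """GLS quantities for W = I + Z diag(theta) Z' via Woodbury."""
    q = len(theta_col)
    if q:
        s = np.sqrt(theta_col)
        a = (s[:, None] * ztz) * s[None, :]
        a[np.diag_indices_from(a)] += 1.0
        ca = np.linalg.cholesky(a)
        logdet_w = 2.0 * np.sum(np.log(np.diag(ca)))
        rhs = np.empty((q, ztx.shape[1] + 1))
        rhs[:, :-1] = s[:, None] * ztx
        rhs[:, -1] = s * zty
        sol = solve_triangular(ca, rhs, lower=True, check_finite=False)
        ax, ay = sol[:, :-1], sol[:, -1]
        xwx = xtx - ax.T @ ax
        xwy = xty - ax.T @ ay
        ywy = yty - ay @ ay
    else:
        logdet_w = 0.0
        xwx, xwy, ywy = xtx, xty, yty
    return xwx, xwy, ywy, logdet_w


def _neg2_profiled(zeta, pre, n, p, reml, level_of_col):
    """-2 log-likelihood profiled over beta and sigma_e^2.

    ``zeta`` holds log(sigma_l/sigma_e) per level.
    """
    xtx, xty, yty, ztx, zty, ztz = pre
    theta_col = np.exp(2.0 * zeta)[level_of_col] if len(zeta) else np.zeros(0)
    xwx, xwy, ywy, logdet_w = _gaussian_pieces(xtx, xty, yty, ztx, zty, ztz, theta_col)
    try:
        cx = np.linalg.cholesky(xwx)
    except np.linalg.LinAlgError:
        return 1e12
    beta = np.linalg.solve(xwx, xwy)
    rss = max(ywy - beta @ xwy, 1e-300)
    if reml:
        dof = n - p
        logdet_xwx = 2.0 * np.sum(np.log(np.diag(cx)))
        return dof * (np.log(2.0 * np.pi * rss / dof) + 1.0) + logdet_w + logdet_xwx
    return n * (np.log(2.0 * np.pi * rss / n) + 1.0) + logdet_w


def _neg2_unprofiled(log_sigmas, pre, n, p, reml, level_of_col):
    """-2 log-likelihood as a function of (log sigma_1..L, log sigma_e)."""
    xtx, xty, yty, ztx, zty, ztz = pre
    sig = np.exp(log_sigmas)
    sigma_e2 = sig[-1] ** 2
    theta = (sig[:-1] ** 2) / sigma_e2
    theta_col = theta[level_of_col] if len(theta) else np.zeros(0)
    xwx, xwy, ywy, logdet_w = _gaussian_pieces(xtx, xty, yty, ztx, zty, ztz, theta_col)
    try:
        cx = np.linalg.cholesky(xwx)
    except np.linalg.LinAlgError:
        return 1e12
    beta = np.linalg.solve(xwx, xwy)
    rss = max(ywy - beta @ xwy, 1e-300)
    out = n * np.log(sigma_e2) + logdet_w + rss / sigma_e2 + n * np.log(2.0 * np.pi)
    if reml:
        logdet_xwx = 2.0 * np.sum(np.log(np.diag(cx)))
        out += logdet_xwx - p * np.log(sigma_e2)
        out -= p * np.log(2.0 * np.pi)
    return out


def fit_gaussian(x, y, design: RandomDesign, reml=True, sd_ci=True) -> GaussianFit:
    """REML/ML fit of y = X beta + sum_l Z_l b_l + e with nested intercepts."""
    n, p = x.shape
    xtx = x.T @ x
    xty = x.T @ y
    yty = float(y @ y)
    ztx = design.z.T @ x
    zty = design.z.T @ y
    ztz = design.z.T @ design.z
    pre = (xtx, xty, yty, ztx, zty, ztz)
    nlev = design.n_levels
    level_of_col = design.col_level

    converged = True
    if nlev:
        args = (pre, n, p, reml, level_of_col)
        opts = {"maxiter": MAX_ITER, "ftol": CONV_TOL, "gtol": 1e-7}
        best = optimize.minimize(
            _neg2_profiled, np.full(nlev, -0.5), args=args,
            method="L-BFGS-B", bounds=[_LOG_RATIO_BOUNDS] * nlev, options=opts,
        )
        # retry from a near-zero-variance start if the first solve failed
        # or parked every ratio at the lower boundary
        if not best.success or np.all(best.x <= _LOG_RATIO_BOUNDS[0] + 1e-6):
            res = optimize.minimize(
                _neg2_profiled, np.full(nlev, -2.5), args=args,
                method="L-BFGS-B", bounds=[_LOG_RATIO_BOUNDS] * nlev, options=opts,
            )
            if res.fun < best.fun - 1e-10:
                best = res
        zeta = best.x
        converged = bool(best.success) or best.fun < 1e11
    else:
        zeta = np.zeros(0)

    theta = np.exp(2.0 * zeta)
    theta_col = theta[level_of_col] if nlev else np.zeros(0)
    xwx, xwy, ywy, _ = _gaussian_pieces(*pre, theta_col)
    try:
        beta = np.linalg.solve(xwx, xwy)
        xwx_inv = np.linalg.inv(xwx)
    except np.linalg.LinAlgError:
        # rank-deficient fixed effects: pseudo-inverse solution; the
        # degenerate directions surface as zero-variance coefficients
        xwx_inv = np.linalg.pinv(xwx)
        beta = xwx_inv @ xwy
    rss = max(ywy - beta @ xwy, 1e-300)
    dof = (n - p) if reml else n
    sigma_e2 = rss / dof
    sigma_e = float(np.sqrt(sigma_e2))
    cov_beta = sigma_e2 * xwx_inv
    sigma_levels = sigma_e * np.exp(zeta)

    # BLUPs: b = Theta Z' W^-1 r
    r_zy = zty - ztx @ beta
    if design.q:
        s = np.sqrt(theta_col)
        a = np.eye(design.q) + (s[:, None] * ztz) * s[None, :]
        t = r_zy - (ztz * s[None, :]) @ np.linalg.solve(a, s * r_zy)
        blup = theta_col * t
    else:
        blup = np.zeros(0)
    fitted_marginal = x @ beta
    fitted_conditional = fitted_marginal + design.z @ blup

    loglik = -0.5 * _neg2_unprofiled(
        np.log(np.concatenate([np.maximum(sigma_levels, 1e-12), [sigma_e]])),
        pre, n, p, reml, level_of_col,
    )

    boundary = zeta <= _LOG_RATIO_BOUNDS[0] + 1e-6 if nlev else np.zeros(0, bool)
    if sd_ci:
        sigma_se_log = _log_sd_se_gaussian(pre, n, p, reml, level_of_col,
                                           sigma_levels, sigma_e, boundary)
    else:
        sigma_se_log = np.full(nlev, np.inf)

    return GaussianFit(
        beta=beta, cov_beta=cov_beta, sigma_resid=sigma_e,
        sigma_levels=np.asarray(sigma_levels), sigma_se_log=sigma_se_log,
        boundary=np.asarray(boundary, bool), loglik=float(loglik), reml=reml,
        blup=blup, fitted_marginal=fitted_marginal,
        fitted_conditional=fitted_conditional, converged=converged,
    )


def _log_sd_se_gaussian(pre, n, p, reml, level_of_col, sigma_levels, sigma_e, boundary):
    """Asymptotic SEs of log(sigma_l) from the numerical Hessian of -2ll."""
    nlev = len(sigma_levels)
    if nlev == 0:
        return np.zeros(0)
    x0 = np.log(np.concatenate([np.maximum(sigma_levels, 1e-8 * sigma_e), [sigma_e]]))
    h = 1e-4
    k = len(x0)
    hess = np.zeros((k, k))
    f0 = _neg2_unprofiled(x0, pre, n, p, reml, level_of_col)
    for i in range(k):
        for j in range(i, k):
            xi = x0.copy(); xi[i] += h; xi[j] += h
            xj = x0.copy(); xj[i] += h; xj[j] -= h
            xk = x0.copy(); xk[i] -= h; xk[j] += h
            xl = x0.copy(); xl[i] -= h; xl[j] -= h
            val = (
                _neg2_unprofiled(xi, pre, n, p, reml, level_of_col)
                - _neg2_unprofiled(xj, pre, n, p, reml, level_of_col)
                - _neg2_unprofiled(xk, pre, n, p, reml, level_of_col)
                + _neg2_unprofiled(xl, pre, n, p, reml, level_of_col)
            ) / (4.0 * h * h)
            hess[i, j] = hess[j, i] = val
    del f0
    se = np.full(nlev, np.inf)
    try:
        cov = 2.0 * np.linalg.inv(hess)
        diag = np.diag(cov)[:nlev]
        good = diag > 0
        se[good] = np.sqrt(diag[good])
    except np.linalg.LinAlgError:
        pass
    se[np.asarray(boundary, bool)] = np.inf
    return se


# ---------------------------------------------------------------------------
# Binomial-logit GLMM via Laplace approximation
# ---------------------------------------------------------------------------


@dataclass
class BinomialFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_levels: np.ndarray
    sigma_se_log: np.ndarray
    boundary: np.ndarray
    loglik: float
    blup: np.ndarray
    fitted_marginal: np.ndarray      # probabilities from X beta only
    fitted_conditional: np.ndarray   # probabilities including BLUPs
    linear_predictor: np.ndarray     # X beta + Z b
    converged: bool


def _inner_modes(beta, dinv_col, x, z, y, b0):
    """Newton solve for the random-effect modes given beta and D^-1."""
    b = b0.copy()
    xb = x @ beta
    for _ in range(100):
        eta = xb + z @ b
        mu = special.expit(eta)
        grad = z.T @ (y - mu) - dinv_col * b
        w = mu * (1.0 - mu)
        hess = (z.T * w) @ z
        hess[np.diag_indices_from(hess)] += dinv_col
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return b, hess


def _laplace_neg_loglik(params, x, z, y, level_of_col, p, nlev, state):
    beta = params[:p]
    log_sig = params[p:]
    sig2 = np.exp(2.0 * log_sig)
    if z.shape[1]:
        dinv_col = 1.0 / np.maximum(sig2[level_of_col], 1e-12)
        b, hess = _inner_modes(beta, dinv_col, x, z, y, state["b"])
        state["b"] = b
        eta = x @ beta + z @ b
        ll = float(y @ eta - np.sum(np.logaddexp(0.0, eta)))
        ll -= 0.5 * float(b @ (dinv_col * b))
        sign, logdet_h = np.linalg.slogdet(hess)
        if sign <= 0:
            return 1e12
        # log det(D^{1/2} H D^{1/2}) = log det H + sum log d
        ll -= 0.5 * (logdet_h + np.sum(np.log(np.maximum(sig2[level_of_col], 1e-12))))
    else:
        eta = x @ beta
        ll = float(y @ eta - np.sum(np.logaddexp(0.0, eta)))
    return -ll


def fit_binomial(x, y, design: RandomDesign) -> BinomialFit:
    """Laplace-approximate ML fit of a logit GLMM with nested intercepts."""
    n, p = x.shape
    y = np.asarray(y, float)
    if np.all(y == y[0]):
        raise SeparationError("response is constant; the model is separated")
    z = design.z
    nlev = design.n_levels
    level_of_col = design.col_level

    # start at the fixed-effects-only solution (own IRLS to stay self-contained)
    beta0 = np.zeros(p)
    for _ in range(50):
        eta = x @ beta0
        mu = special.expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        zadj = eta + (y - mu) / w
        xtwx = (x.T * w) @ x
        try:
            beta_new = np.linalg.solve(xtwx, (x.T * w) @ zadj)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(xtwx, (x.T * w) @ zadj, rcond=None)[0]
        if np.max(np.abs(beta_new - beta0)) < 1e-9:
            beta0 = beta_new
            break
        beta0 = beta_new
    if np.max(np.abs(beta0)) > 25.0:
        raise SeparationError(
            "fixed-effects logistic fit diverged (|beta| > 25); "
            "a predictor separates the response"
        )

    state = {"b": np.zeros(design.q)}
    x0 = np.concatenate([beta0, np.full(nlev, np.log(0.3))])
    bounds = [(-30.0, 30.0)] * p + [(-6.0, 3.0)] * nlev
    res = optimize.minimize(
        _laplace_neg_loglik, x0,
        args=(x, z, y, level_of_col, p, nlev, state),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": MAX_ITER, "ftol": CONV_TOL},
    )
    params = res.x
    beta = params[:p]
    log_sig = params[p:]
    if np.max(np.abs(beta)) >= 29.5:
        raise SeparationError("coefficient diverged to the optimizer bound")
    sigma_levels = np.exp(log_sig)
    boundary = log_sig <= -6.0 + 1e-6 if nlev else np.zeros(0, bool)

    sig2 = np.exp(2.0 * log_sig)
    if design.q:
        dinv_col = 1.0 / np.maximum(sig2[level_of_col], 1e-12)
        b, hess = _inner_modes(beta, dinv_col, x, z, y, state["b"])
        eta = x @ beta + z @ b
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        xtwx = (x.T * w) @ x
        xtwz = (x.T * w) @ z
        try:
            cov_beta = np.linalg.inv(xtwx - xtwz @ np.linalg.solve(hess, xtwz.T))
        except np.linalg.LinAlgError:
            cov_beta = np.linalg.pinv(xtwx)
    else:
        b = np.zeros(0)
        eta = x @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        cov_beta = np.linalg.inv((x.T * w) @ x)

    sigma_se_log = _log_sd_se_binomial(
        params, x, z, y, level_of_col, p, nlev, state, boundary
    )

    return BinomialFit(
        beta=beta, cov_beta=cov_beta, sigma_levels=sigma_levels,
        sigma_se_log=sigma_se_log, boundary=np.asarray(boundary, bool),
        loglik=float(-res.fun), blup=b,
        fitted_marginal=special.expit(x @ beta),
        fitted_conditional=mu, linear_predictor=eta,
        converged=bool(res.success),
    )


def _log_sd_se_binomial(params, x, z, y, level_of_col, p, nlev, state, boundary):
    if nlev == 0:
        return np.zeros(0)
    h = 1e-3
    idx = np.arange(p, p + nlev)
    hess = np.zeros((nlev, nlev))
    for a in range(nlev):
        for c in range(a, nlev):
            pp = params.copy(); pp[idx[a]] += h; pp[idx[c]] += h
            pm = params.copy(); pm[idx[a]] += h; pm[idx[c]] -= h
            mp = params.copy(); mp[idx[a]] -= h; mp[idx[c]] += h
            mm = params.copy(); mm[idx[a]] -= h; mm[idx[c]] -= h
            args = (x, z, y, level_of_col, p, nlev, state)
            val = (
                _laplace_neg_loglik(pp, *args) - _laplace_neg_loglik(pm, *args)
                - _laplace_neg_loglik(mp, *args) + _laplace_neg_loglik(mm, *args)
            ) / (4.0 * h * h)
            hess[a, c] = hess[c, a] = val
    se = np.full(nlev, np.inf)
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        good = diag > 0
        se[good] = np.sqrt(diag[good])
    except np.linalg.LinAlgError:
        pass
    se[np.asarray(boundary, bool)] = np.inf
    return se
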