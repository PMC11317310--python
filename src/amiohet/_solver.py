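"""Low-level numerical kernels (numba-compiled).

Two solvers live here:

* an IRLS + cyclic coordinate-descent path solver for the weighted,
  L1-penalized binomial log-likelihood with per-feature penalty factors
  (glmnet-style quadratic approximation with warm starts along the
  lambda path);
* a damped Newton-Raphson solver for the unpenalized weighted logistic
  MLE, returning the observed-information covariance for Wald intervals.

Inputs are expected already standardized/normalized by the callers in
:mod:`amiohet.penalized` and :mod:`amiohet.inference`; nothing here knows
about pandas or original covariate scales.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Floor on the IRLS variance p*(1-p), as in glmnet, to keep working
# weights bounded when fitted probabilities saturate.
_VAR_FLOOR = 1e-5


@njit(cache=True)
def _soft_threshold(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


@njit(cache=True, fastmath=True)
def cd_logistic_path(X, y, w, pf, lambdas, fit_intercept, tol, max_irls, max_cd):
    """Coordinate-descent path for weighted L1 logistic regression.

    Minimizes (1/n) sum_i w_i * log(1 + exp(-(2 y_i - 1) * eta_i))
    + lam * sum_j pf_j |beta_j|, with eta = b0 + X beta (b0 present only
    when ``fit_intercept``). ``w`` must average to 1; ``X`` must already
    be on the scale the penalty is meant to apply to.

    Returns (intercepts, coefs) over the lambda path, warm-started from
    large to small lambda.
    """
    n, p = X.shape
    n_lam = lambdas.shape[0]
    coefs = np.zeros((n_lam, p))
    icepts = np.zeros(n_lam)

    beta = np.zeros(p)
    b0 = 0.0
    if fit_intercept:
        mu = 0.0
        sw = 0.0
        for i in range(n):
            mu += w[i] * y[i]
            sw += w[i]
        mu /= sw
        if mu < 1e-10:
            mu = 1e-10
        if mu > 1.0 - 1e-10:
            mu = 1.0 - 1e-10
        b0 = np.log(mu / (1.0 - mu))

    eta = np.empty(n)
    for i in range(n):
        eta[i] = b0

    vw = np.empty(n)
    r = np.empty(n)
    xv = np.empty(p)          # per-IRLS curvature sum_i vw_i x_ij^2 / n
    active = np.zeros(p, dtype=np.bool_)

    for l in range(n_lam):
        lam = lambdas[l]
        for _irls in range(max_irls):
            # working response z and weights vw around current eta;
            # r holds the residual z - eta of the current linear fit
            sw = 0.0
            for i in range(n):
                pi = 1.0 / (1.0 + np.exp(-eta[i]))
                var = pi * (1.0 - pi)
                if var < _VAR_FLOOR:
                    var = _VAR_FLOOR
                vw[i] = w[i] * var
                sw += vw[i]
                r[i] = (y[i] - pi) / var
            for j in range(p):
                acc = 0.0
                for i in range(n):
                    acc += vw[i] * X[i, j] * X[i, j]
                xv[j] = acc / n

            # full sweeps alternate with sweeps over the active set only
            irls_delta = 0.0
            full_sweep = True
            for _sweep in range(max_cd):
                maxd = 0.0
                if fit_intercept:
                    num = 0.0
                    for i in range(n):
                        num += vw[i] * r[i]
                    d = num / sw
                    if d != 0.0:
                        b0 += d
                        for i in range(n):
                            r[i] -= d
                        if abs(d) > maxd:
                            maxd = abs(d)
                for j in range(p):
                    if not full_sweep and not active[j]:
                        continue
                    if xv[j] <= 0.0:
                        continue
                    bj = beta[j]
                    num = 0.0
                    for i in range(n):
                        num += vw[i] * X[i, j] * r[i]
                    nb = _soft_threshold(num / n + xv[j] * bj, lam * pf[j]) / xv[j]
                    d = nb - bj
                    if d != 0.0:
                        beta[j] = nb
                        active[j] = nb != 0.0
                        for i in range(n):
                            r[i] -= X[i, j] * d
                        if abs(d) > maxd:
                            maxd = abs(d)
                if maxd > irls_delta:
                    irls_delta = maxd
                if maxd < tol:
                    if full_sweep:
                        break
                    full_sweep = True  # converged on active set; verify with full sweep
                else:
                    full_sweep = False
            # recompute eta exactly from coefficients to avoid drift
            for i in range(n):
                acc = b0
                for j in range(p):
                    if beta[j] != 0.0:
                        acc += X[i, j] * beta[j]
                eta[i] = acc
            if irls_delta < tol:
                break
        icepts[l] = b0
        coefs[l, :] = beta
    return icepts, coefs


@njit(cache=True, fastmath=True)
def binomial_deviance(y, eta, w):
    """Mean weighted binomial deviance, -2/W * sum w_i loglik_i."""
    n = y.shape[0]
    tot = 0.0
    sw = 0.0
    for i in range(n):
        e = eta[i]
        # log(1 + exp(-|e|)) + max(0, -s*e) is the stable -loglik
        if y[i] > 0.5:
            z = -e
        else:
            z = e
        if z > 30.0:
            ll = z
        else:
            ll = np.log1p(np.exp(z))
        tot += w[i] * ll
        sw += w[i]
    return 2.0 * tot / sw


@njit(cache=True)
def newton_logistic(X, y, w, max_iter, tol):
    """Damped Newton-Raphson for the unpenalized weighted logistic MLE.

    Returns (beta, cov, converged, separated). ``separated`` is a
    heuristic flag: fitted linear predictors run away (|eta| > 30 for
    some observation together with a step that stopped improving), which
    is the signature of (quasi-)complete separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    eta = np.zeros(n)
    converged = False
    separated = False

    def _nll(e):
        tot = 0.0
        for i in range(n):
            if y[i] > 0.5:
                z = -e[i]
            else:
                z = e[i]
            if z > 30.0:
                tot += w[i] * z
            else:
                tot += w[i] * np.log1p(np.exp(z))
        return tot

    nll = _nll(eta)
    H = np.zeros((p, p))
    for _it in range(max_iter):
        grad = np.zeros(p)
        for a in range(p):
            for b in range(p):
                H[a, b] = 0.0
        for i in range(n):
            pi = 1.0 / (1.0 + np.exp(-eta[i]))
            ww = w[i] * pi * (1.0 - pi)
            resid = w[i] * (y[i] - pi)
            for a in range(p):
                grad[a] += X[i, a] * resid
                xa = X[i, a] * ww
                for b in range(a, p):
                    H[a, b] += xa * X[i, b]
        for a in range(p):
            for b in range(a + 1, p):
                H[b, a] = H[a, b]
            H[a, a] += 1e-10  # numerical ridge
        step = np.linalg.solve(H, grad)
        # backtracking line search on the negative log-likelihood
        scale = 1.0
        improved = False
        for _half in range(30):
            cand = beta + scale * step
            eta_c = X @ cand
            nll_c = _nll(eta_c)
            if nll_c <= nll + 1e-9 * (abs(nll) + 1.0):
                beta = cand
                eta = eta_c
                nll = nll_c
                improved = True
                break
            scale *= 0.5
        maxstep = 0.0
        fullstep = 0.0
        for a in range(p):
            if abs(scale * step[a]) > maxstep:
                maxstep = abs(scale * step[a])
            if abs(step[a]) > fullstep:
                fullstep = abs(step[a])
        if improved and maxstep < tol:
            converged = True
            break
        if not improved:
            # no admissible step: at the optimum within float precision
            # when the proposed Newton step is already negligible
            if fullstep < 1e-5:
                converged = True
            break

    if not converged:
        # ran out of iterations or stalled away from a stationary point:
        # diverging coefficients are the signature of separation
        maxeta = 0.0
        for i in range(n):
            if abs(eta[i]) > maxeta:
                maxeta = abs(eta[i])
        if maxeta > 30.0:
            separated = True

    # observed information based covariance at the solution
    for a in range(p):
        for b in range(p):
            H[a, b] = 0.0
    for i in range(n):
        pi = 1.0 / (1.0 + np.exp(-eta[i]))
        ww = w[i] * pi * (1.0 - pi)
        for a in range(p):
            xa = X[i, a] * ww
            for b in range(a, p):
                H[a, b] += xa * X[i, b]
    for a in range(p):
        for b in range(a + 1, p):
            H[b, a] = H[a, b]
        H[a, a] += 1e-10
    cov = np.linalg.inv(H)
    return beta, cov, converged, separated
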