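"""Numba-compiled scalar kernels for the single-point gradient path.

The sampler evaluates log-density and gradient at one parameter point tens
of thousands of times per fit; the vectorized numpy implementations in
:mod:`thetasync.bayes.models` pay ~100 microseconds of array overhead per
call, which these explicit-loop kernels avoid.  They implement *exactly*
the same formulas; a test asserts agreement with the numpy path to float
precision.  If numba is unavailable the package silently falls back to
numpy.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap

_LOG_2PI = math.log(2.0 * math.pi)
_SQRT_2PI = math.sqrt(2.0 * math.pi)
_INV_SQRT2 = 1.0 / math.sqrt(2.0)


@njit(cache=True)
def _digamma(x: float) -> float:
    """Psi function for x > 0: recurrence into the asymptotic series."""
    r = 0.0
    while x < 6.0:
        r -= 1.0 / x
        x += 1.0
    f = 1.0 / (x * x)
    return (r + math.log(x) - 0.5 / x
            - f * (1.0 / 12.0 - f * (1.0 / 120.0 - f * (1.0 / 252.0
                   - f * (1.0 / 240.0 - f * (1.0 / 132.0))))))


@njit(cache=True)
def _beta_kernel(theta, X, Xv, subj, n_subj, log_y, log_1my, logit_y,
                 coef_sd, v_shape, v_rate, phi_shape, phi_rate, want_grad):
    n, p = X.shape
    q = Xv.shape[1]
    beta = theta[:p]
    sig = np.exp(theta[p : p + q])
    z = theta[p + q : p + q + n_subj * q].copy().reshape(n_subj, q)
    log_phi = theta[-1]
    phi = math.exp(log_phi)
    sum_log_y = 0.0
    sum_log1my = 0.0
    for i in range(n):
        sum_log_y += log_y[i]
        sum_log1my += log_1my[i]

    grad = np.zeros_like(theta)
    gz = np.zeros((n_subj, q))
    gls = np.zeros(q)
    ll = n * math.lgamma(phi) - sum_log_y - sum_log1my + phi * sum_log1my
    dphi_acc = n * _digamma(phi) + sum_log1my
    psi_phi_terms = 0.0
    for i in range(n):
        eta = 0.0
        for k in range(p):
            eta += beta[k] * X[i, k]
        s = subj[i]
        for k in range(q):
            eta += Xv[i, k] * z[s, k] * sig[k]
        mu = 1.0 / (1.0 + math.exp(-eta))
        if mu < 1e-12:
            mu = 1e-12
        elif mu > 1.0 - 1e-12:
            mu = 1.0 - 1e-12
        a = mu * phi
        b = (1.0 - mu) * phi
        ll += phi * mu * logit_y[i] - math.lgamma(a) - math.lgamma(b)
        if want_grad:
            psi_a = _digamma(a)
            psi_b = _digamma(b)
            g = phi * mu * (1.0 - mu) * (psi_b - psi_a + logit_y[i])
            for k in range(p):
                grad[k] += g * X[i, k]
            for k in range(q):
                gz[s, k] += g * Xv[i, k] * sig[k]
                gls[k] += g * Xv[i, k] * z[s, k] * sig[k]
            dphi_acc += -(mu * (psi_a - logit_y[i])) - (1.0 - mu) * psi_b
    lp = ll + phi_shape * log_phi - phi_rate * phi
    for k in range(p):
        lp += -0.5 * (beta[k] / coef_sd) ** 2 - math.log(coef_sd) - 0.5 * _LOG_2PI
    for k in range(q):
        lp += v_shape * math.log(sig[k]) - v_rate * sig[k]
    for s in range(n_subj):
        for k in range(q):
            lp += -0.5 * z[s, k] * z[s, k] - 0.5 * _LOG_2PI
    if want_grad:
        for k in range(p):
            grad[k] -= beta[k] / (coef_sd * coef_sd)
        for k in range(q):
            grad[p + k] = gls[k] + v_shape - v_rate * sig[k]
        for s in range(n_subj):
            for k in range(q):
                grad[p + q + s * q + k] = gz[s, k] - z[s, k]
        grad[-1] = phi * dphi_acc + phi_shape - phi_rate * phi
    return lp, grad


@njit(cache=True)
def _student_kernel(theta, X, Xv, subj, n_subj, y,
                    coef_sd, v_shape, v_rate, resid_scale, resid_df,
                    nu_shape, nu_rate, want_grad):
    n, p = X.shape
    q = Xv.shape[1]
    beta = theta[:p]
    sig = np.exp(theta[p : p + q])
    z = theta[p + q : p + q + n_subj * q].copy().reshape(n_subj, q)
    log_s = theta[-2]
    log_nu = theta[-1]
    s_ = math.exp(log_s)
    nu = math.exp(log_nu)

    grad = np.zeros_like(theta)
    gz = np.zeros((n_subj, q))
    gls = np.zeros(q)
    const = (math.lgamma((nu + 1.0) / 2.0) - math.lgamma(nu / 2.0)
             - 0.5 * math.log(nu * math.pi) - math.log(s_))
    ll = n * const
    dls_acc = 0.0
    dnu_acc = 0.0
    half_dig = 0.5 * _digamma((nu + 1.0) / 2.0) - 0.5 * _digamma(nu / 2.0) \
        - 0.5 / nu
    for i in range(n):
        eta = 0.0
        for k in range(p):
            eta += beta[k] * X[i, k]
        sj = subj[i]
        for k in range(q):
            eta += Xv[i, k] * z[sj, k] * sig[k]
        r = (y[i] - eta) / s_
        r2 = r * r
        A = 1.0 + r2 / nu
        ll += -(nu + 1.0) / 2.0 * math.log(A)
        if want_grad:
            denom = nu + r2
            g = (nu + 1.0) * r / (s_ * denom)
            for k in range(p):
                grad[k] += g * X[i, k]
            for k in range(q):
                gz[sj, k] += g * Xv[i, k] * sig[k]
                gls[k] += g * Xv[i, k] * z[sj, k] * sig[k]
            dls_acc += -1.0 + (nu + 1.0) * r2 / denom
            dnu_acc += half_dig - 0.5 * math.log(A) \
                + (nu + 1.0) * r2 / (2.0 * nu * denom)
    lp = ll
    for k in range(p):
        lp += -0.5 * (beta[k] / coef_sd) ** 2 - math.log(coef_sd) - 0.5 * _LOG_2PI
    for k in range(q):
        lp += v_shape * math.log(sig[k]) - v_rate * sig[k]
    for sj in range(n_subj):
        for k in range(q):
            lp += -0.5 * z[sj, k] * z[sj, k] - 0.5 * _LOG_2PI
    # half-student-t prior on the residual scale (+ Jacobian)
    lp += (math.lgamma((resid_df + 1.0) / 2.0) - math.lgamma(resid_df / 2.0)
           - 0.5 * math.log(resid_df * math.pi) - math.log(resid_scale)
           - (resid_df + 1.0) / 2.0
           * math.log(1.0 + (s_ / resid_scale) ** 2 / resid_df)
           + math.log(2.0) + log_s)
    lp += nu_shape * log_nu - nu_rate * nu
    if want_grad:
        for k in range(p):
            grad[k] -= beta[k] / (coef_sd * coef_sd)
        for k in range(q):
            grad[p + k] = gls[k] + v_shape - v_rate * sig[k]
        for sj in range(n_subj):
            for k in range(q):
                grad[p + q + sj * q + k] = gz[sj, k] - z[sj, k]
        grad[-2] = dls_acc + 1.0 - (resid_df + 1.0) * s_ * s_ \
            / (resid_df * resid_scale * resid_scale + s_ * s_)
        grad[-1] = nu * dnu_acc + nu_shape - nu_rate * nu
    return lp, grad


@njit(cache=True)
def _ordinal_kernel(theta, X, Xv, subj, n_subj, yk, n_thresh,
                    coef_sd, v_shape, v_rate, want_grad):
    n, p = X.shape
    q = Xv.shape[1]
    beta = theta[:p]
    c = np.empty(n_thresh)
    c[0] = theta[p]
    for j in range(1, n_thresh):
        c[j] = c[j - 1] + math.exp(theta[p + j])
    off = p + n_thresh
    sig = np.exp(theta[off : off + q])
    z = theta[off + q : off + q + n_subj * q].copy().reshape(n_subj, q)

    grad = np.zeros_like(theta)
    gz = np.zeros((n_subj, q))
    gls = np.zeros(q)
    dC = np.zeros(n_thresh)
    ll = 0.0
    for i in range(n):
        eta = 0.0
        for k in range(p):
            eta += beta[k] * X[i, k]
        sj = subj[i]
        for k in range(q):
            eta += Xv[i, k] * z[sj, k] * sig[k]
        ki = yk[i]
        if ki <= n_thresh:
            u = c[ki - 1] - eta
            cdf_u = 0.5 * math.erfc(-u * _INV_SQRT2)
            pdf_u = math.exp(-0.5 * u * u) / _SQRT_2PI
        else:
            cdf_u = 1.0
            pdf_u = 0.0
        if ki >= 2:
            l = c[ki - 2] - eta
            cdf_l = 0.5 * math.erfc(-l * _INV_SQRT2)
            pdf_l = math.exp(-0.5 * l * l) / _SQRT_2PI
        else:
            cdf_l = 0.0
            pdf_l = 0.0
        prob = cdf_u - cdf_l
        if prob < 1e-300:
            prob = 1e-300
        ll += math.log(prob)
        if want_grad:
            g = (pdf_l - pdf_u) / prob
            for k in range(p):
                grad[k] += g * X[i, k]
            for k in range(q):
                gz[sj, k] += g * Xv[i, k] * sig[k]
                gls[k] += g * Xv[i, k] * z[sj, k] * sig[k]
            if ki <= n_thresh:
                dC[ki - 1] += pdf_u / prob
            if ki >= 2:
                dC[ki - 2] -= pdf_l / prob
    lp = ll
    for k in range(p):
        lp += -0.5 * (beta[k] / coef_sd) ** 2 - math.log(coef_sd) - 0.5 * _LOG_2PI
    for j in range(n_thresh):
        lp += -0.5 * (c[j] / coef_sd) ** 2 - math.log(coef_sd) - 0.5 * _LOG_2PI
    for j in range(1, n_thresh):
        lp += theta[p + j]                           # Jacobian of increments
    for k in range(q):
        lp += v_shape * math.log(sig[k]) - v_rate * sig[k]
    for sj in range(n_subj):
        for k in range(q):
            lp += -0.5 * z[sj, k] * z[sj, k] - 0.5 * _LOG_2PI
    if want_grad:
        for k in range(p):
            grad[k] -= beta[k] / (coef_sd * coef_sd)
        for j in range(n_thresh):
            dC[j] -= c[j] / (coef_sd * coef_sd)      # threshold prior
        acc = 0.0
        for j in range(n_thresh - 1, 0, -1):
            acc += dC[j]
            grad[p + j] = math.exp(theta[p + j]) * acc + 1.0
        grad[p] = acc + dC[0]
        for k in range(q):
            grad[off + k] = gls[k] + v_shape - v_rate * sig[k]
        for sj in range(n_subj):
            for k in range(q):
                grad[off + q + sj * q + k] = gz[sj, k] - z[sj, k]
    return lp, grad
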