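"""Whole-chain No-U-Turn sampler compiled with numba.

One generic driver runs a full NUTS chain for any of the three model
families, dispatching to the compiled likelihood kernels from
:mod:`thetasync.bayes._kernels`.  The tree is built iteratively with
O(max_depth) checkpoint storage: within a subtree of 2^j sequential
leapfrog leaves, every balanced sub-subtree's no-U-turn condition is
checked against checkpointed endpoint states using the standard
power-of-two bookkeeping.  Candidate draws are reservoir-sampled uniformly
among slice-acceptable leaves (the classic slice formulation).

Warmup follows the usual three-phase schedule: an initial step-size-only
buffer, a window whose draws set a diagonal metric, a second window whose
draws set a dense metric (shrunk toward its diagonal), and a final buffer
that re-tunes the step size under the frozen metric.  Dual averaging
targets a configurable acceptance statistic.

The Python implementation in :mod:`thetasync.bayes.sampler` mirrors this
algorithm and serves as the fallback and reference.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap

from ._kernels import _beta_kernel, _ordinal_kernel, _student_kernel

_DELTA_MAX = 1000.0

FAMILY_BETA = 0
FAMILY_STUDENT = 1
FAMILY_ORDINAL = 2

# hyper vector layout (float64):
# 0 coef_sd | 1 v_shape | 2 v_rate | 3 phi_shape | 4 phi_rate
# 5 resid_scale | 6 resid_df | 7 nu_shape | 8 nu_rate | 9 n_thresh | 10 n_subj


@njit(cache=True)
def _nuts_chain(family, X, Xv, subj, arr1, arr2, arr3, iarr, hyper,
                ndim, n_samples, n_warmup, max_depth, target_accept, seed):
    np.random.seed(seed)
    n_subj = int(hyper[10])
    n_thresh = int(hyper[9])

    def kernel(theta):
        if family == 0:
            return _beta_kernel(theta, X, Xv, subj, n_subj, arr1, arr2, arr3,
                                hyper[0], hyper[1], hyper[2], hyper[3],
                                hyper[4], True)
        elif family == 1:
            return _student_kernel(theta, X, Xv, subj, n_subj, arr1,
                                   hyper[0], hyper[1], hyper[2], hyper[5],
                                   hyper[6], hyper[7], hyper[8], True)
        else:
            return _ordinal_kernel(theta, X, Xv, subj, n_subj, iarr, n_thresh,
                                   hyper[0], hyper[1], hyper[2], True)

    inv_mass = np.eye(ndim)
    mom_chol = np.eye(ndim)

    q = np.zeros(ndim)
    lp, grad = kernel(q)

    n_kept = n_samples - n_warmup
    kept = np.empty((n_kept, ndim))
    warm = np.empty((n_warmup if n_warmup > 0 else 1, ndim))
    n_divergent = 0

    # --- initial step size heuristic
    eps = 1.0
    p0 = mom_chol @ np.random.standard_normal(ndim)
    h0 = lp - 0.5 * p0 @ (inv_mass @ p0)
    ph = p0 + 0.5 * eps * grad
    qh = q + eps * (inv_mass @ ph)
    lph, gradh = kernel(qh)
    ph = ph + 0.5 * eps * gradh
    h1 = lph - 0.5 * ph @ (inv_mass @ ph)
    diff = h1 - h0 if np.isfinite(h1) else -np.inf
    direction = 1.0 if diff > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        ph = p0 + 0.5 * eps * grad
        qh = q + eps * (inv_mass @ ph)
        lph, gradh = kernel(qh)
        ph = ph + 0.5 * eps * gradh
        h1 = lph - 0.5 * ph @ (inv_mass @ ph)
        diff = h1 - h0 if np.isfinite(h1) else -np.inf
        if direction * diff <= direction * np.log(0.5):
            break

    # --- dual averaging state
    mu_da = np.log(10.0 * eps)
    log_eps = np.log(eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    m_da = 0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75

    # --- warmup schedule
    if n_warmup >= 200:
        a_end = n_warmup // 4
        w1_end = n_warmup // 2
        w2_end = n_warmup - max(50, n_warmup // 10)
    else:
        a_end = n_warmup + 1
        w1_end = n_warmup + 1
        w2_end = n_warmup + 1

    ck_q = np.empty((max_depth + 1, ndim))
    ck_p = np.empty((max_depth + 1, ndim))

    for it in range(n_samples):
        warming = it < n_warmup
        depth_cap = max_depth
        if warming and it < w1_end:
            depth_cap = min(6, max_depth)

        p0 = mom_chol @ np.random.standard_normal(ndim)
        h0 = lp - 0.5 * p0 @ (inv_mass @ p0)
        logu = h0 + np.log(np.random.random())

        qm = q.copy(); pm = p0.copy(); gm = grad.copy()
        qp = q.copy(); pp = p0.copy(); gp = grad.copy()
        qs = q.copy(); lps = lp; gs = grad.copy()
        n_tot = 1
        s_ok = True
        depth = 0
        alpha_sum = 0.0
        n_alpha = 0
        diverged = False

        while s_ok and depth < depth_cap:
            v = 1.0 if np.random.random() < 0.5 else -1.0
            if v > 0:
                qq = qp.copy(); pq = pp.copy(); gq = gp.copy()
            else:
                qq = qm.copy(); pq = pm.copy(); gq = gm.copy()
            n_sub = 0
            s_sub = True
            n_leaf = 1 << depth
            q_cand = qs; lp_cand = lps; g_cand = gs  # placeholders
            have_cand = False
            for i in range(n_leaf):
                # leapfrog in direction v
                pq = pq + 0.5 * v * eps * gq
                qq = qq + v * eps * (inv_mass @ pq)
                lpq, gq = kernel(qq)
                pq = pq + 0.5 * v * eps * gq
                if np.isfinite(lpq):
                    h1 = lpq - 0.5 * pq @ (inv_mass @ pq)
                else:
                    h1 = -np.inf
                if logu <= h1:
                    n_sub += 1
                    if np.random.random() < 1.0 / n_sub:
                        q_cand = qq.copy(); lp_cand = lpq; g_cand = gq.copy()
                        have_cand = True
                d = h1 - h0
                if d > 0.0:
                    d = 0.0
                alpha_sum += np.exp(d) if np.isfinite(d) else 0.0
                n_alpha += 1
                if not (logu < h1 + _DELTA_MAX):
                    s_sub = False
                    diverged = True
                    break
                # checkpoint this leaf at every level 2^s dividing i
                for s_lvl in range(1, depth + 1):
                    if i % (1 << s_lvl) == 0:
                        ck_q[s_lvl] = qq
                        ck_p[s_lvl] = pq
                    else:
                        break
                # balanced subtrees ending at leaf i: no-U-turn checks
                stop = False
                for s_lvl in range(1, depth + 1):
                    if (i + 1) % (1 << s_lvl) == 0:
                        dqt = v * (qq - ck_q[s_lvl])
                        if dqt @ (inv_mass @ ck_p[s_lvl]) < 0.0 or \
                                dqt @ (inv_mass @ pq) < 0.0:
                            stop = True
                            break
                    else:
                        break
                if stop:
                    s_sub = False
                    break
            if v > 0:
                qp = qq; pp = pq; gp = gq
            else:
                qm = qq; pm = pq; gm = gq
            if s_sub and n_sub > 0 and have_cand:
                if np.random.random() < n_sub / n_tot:
                    qs = q_cand; lps = lp_cand; gs = g_cand
            n_tot += n_sub
            dq = qp - qm
            s_ok = s_sub and (dq @ (inv_mass @ pm) >= 0.0) \
                and (dq @ (inv_mass @ pp) >= 0.0)
            depth += 1

        q = qs; lp = lps; grad = gs
        alpha = alpha_sum / n_alpha if n_alpha > 0 else 0.0
        if diverged and not warming:
            n_divergent += 1

        if warming:
            warm[it] = q
            m_da += 1
            h_bar += (target_accept - alpha - h_bar) / (m_da + t0_da)
            log_eps = mu_da - np.sqrt(m_da) / gamma_da * h_bar
            w_da = m_da ** (-kappa_da)
            log_eps_bar = w_da * log_eps + (1.0 - w_da) * log_eps_bar
            eps = np.exp(log_eps)
            if it + 1 == w1_end or it + 1 == w2_end:
                lo = a_end if it + 1 == w1_end else w1_end
                win = warm[lo : it + 1]
                nw = win.shape[0]
                mean = np.zeros(ndim)
                for r in range(nw):
                    mean += win[r]
                mean /= nw
                shrink = nw / (nw + 5.0)
                if it + 1 == w1_end:
                    var = np.zeros(ndim)
                    for r in range(nw):
                        d0 = win[r] - mean
                        var += d0 * d0
                    var /= max(nw - 1, 1)
                    var = shrink * var + (1.0 - shrink) * 1e-3
                    inv_mass = np.diag(var)
                else:
                    cov = np.zeros((ndim, ndim))
                    for r in range(nw):
                        d0 = win[r] - mean
                        cov += np.outer(d0, d0)
                    cov /= max(nw - 1, 1)
                    cov = 0.8 * cov + 0.2 * np.diag(np.diag(cov))
                    cov = shrink * cov + (1.0 - shrink) * 1e-3 * np.eye(ndim)
                    inv_mass = cov
                # momentum covariance = inv(inv_mass): chol then invert
                l_c = np.linalg.cholesky(inv_mass)
                mom_chol = np.linalg.inv(l_c).T.copy()
                # restart dual averaging anchored at the current step size
                mu_da = np.log(10.0 * eps)
                log_eps_bar = 0.0
                h_bar = 0.0
                m_da = 0
        else:
            if it == n_warmup:
                eps = np.exp(log_eps_bar)
            kept[it - n_warmup] = q
    return kept, n_divergent


def run_numba_chain(pack, ndim, n_samples, n_warmup, max_depth,
                    target_accept, seed) -> np.ndarray:
    """Python entry point; ``pack`` comes from the model builders."""
    family, X, Xv, subj, arr1, arr2, arr3, iarr, hyper = pack
    kept, _ = _nuts_chain(
        family, X, Xv, subj, arr1, arr2, arr3, iarr, hyper,
        ndim, n_samples, n_warmup, max_depth, target_accept, np.uint32(seed),
    )
    return kept
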