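"""Log-posteriors (with analytic gradients) of the three model families.

Every model is expressed on an unconstrained parameter vector (scales and
precisions log-transformed, ordinal thresholds as first-threshold plus
log-increments) so a Hamiltonian sampler can explore it.  Subject varying
effects use the non-centered parameterization u_s = z_s * sigma with
z ~ N(0,1), which removes the funnel between deviations and their scale.
``log_prob`` and ``log_prob_grad`` accept a (n_points, ndim) matrix; priors
include the change-of-variable Jacobians.  Gradients are hand-derived and
verified against finite differences in the test suite.

Priors (configurable via :class:`PriorSet`):

* fixed effects and ordinal thresholds: normal(0, 1);
* varying-effect standard deviations: gamma(shape=2, rate=2);
* beta precision phi: gamma(0.01, 0.01);
* student-t residual scale: half-student-t(scale=10, df=3);
* student-t normality df nu: gamma(2, 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln, ndtr

__all__ = [
    "PriorSet",
    "ModelSpec",
    "LogPosterior",
    "beta_ispc_model",
    "student_t_pleasantness_model",
    "ordinal_familiarity_model",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSet:
    """Hyperparameters of the weakly informative prior set."""

    coef_sd: float = 1.0                 # normal sd on slopes/intercepts/thresholds
    varying_shape: float = 2.0           # gamma(shape, rate) on varying-effect sds
    varying_rate: float = 2.0
    phi_shape: float = 0.01              # gamma on the beta precision
    phi_rate: float = 0.01
    resid_scale: float = 10.0            # half-student-t on the residual scale
    resid_df: float = 3.0
    nu_shape: float = 2.0                # gamma on the normality parameter
    nu_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("coef_sd", "varying_shape", "varying_rate", "phi_shape",
                     "phi_rate", "resid_scale", "resid_df", "nu_shape", "nu_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter {name} must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Family plus design options for one model fit."""

    family: str                          # "beta-logit" | "student-t" | "cumulative-probit"
    priors: PriorSet = field(default_factory=PriorSet)
    varying_slopes: bool = True          # subject-varying counterpart of every slope

    def __post_init__(self) -> None:
        if self.family not in ("beta-logit", "student-t", "cumulative-probit"):
            raise ValueError(f"unknown likelihood family {self.family!r}")


class LogPosterior:
    """A vectorized log-density with gradient and named monitored parameters.

    ``fast`` is an optional compiled single-point implementation of the same
    density (see :mod:`thetasync.bayes._kernels`); the vectorized numpy path
    remains the reference and is always available.
    """

    def __init__(self, ndim, logp_grad, monitored, n_obs, fast=None,
                 numba_pack=None):
        self.ndim = int(ndim)
        self._logp_grad = logp_grad
        self.monitored = monitored
        self.n_obs = int(n_obs)
        self._fast = fast
        self.numba_pack = numba_pack

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        out, _ = self._logp_grad(theta, want_grad=False)
        return np.where(np.isfinite(out), out, -np.inf)

    def log_prob_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-density and gradient at one point (1-D input)."""
        th = np.ascontiguousarray(theta, dtype=float)
        if self._fast is not None:
            lp, grad = self._fast(th)
        else:
            lp2, grad2 = self._logp_grad(th[None, :], want_grad=True)
            lp, grad = float(lp2[0]), grad2[0]
        if not np.isfinite(lp):
            return -np.inf, np.zeros(self.ndim)
        return float(lp), grad

    def log_prob_grad_reference(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """The numpy path, bypassing any compiled kernel (for cross-checks)."""
        lp, grad = self._logp_grad(np.asarray(theta, float)[None, :], want_grad=True)
        return float(lp[0]), grad[0]

    def extract(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return {name: fn(theta) for name, fn in self.monitored.items()}


def _hyper_vector(pr: PriorSet, n_thresh: int, n_subj: int) -> np.ndarray:
    """Prior hyperparameters packed for the compiled chain driver."""
    return np.array([
        pr.coef_sd, pr.varying_shape, pr.varying_rate, pr.phi_shape,
        pr.phi_rate, pr.resid_scale, pr.resid_df, pr.nu_shape, pr.nu_rate,
        float(n_thresh), float(n_subj),
    ])


def _subject_codes(subjects) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(pd.Series(subjects).astype(str), sort=True)
    return codes.astype(int), len(uniques)


def _normal_logpdf(x: np.ndarray, sd: float) -> np.ndarray:
    return -0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI


def _gamma_logpdf_log(theta: np.ndarray, shape: float, rate: float) -> np.ndarray:
    # gamma density on x = exp(theta), including the Jacobian x
    return shape * theta - rate * np.exp(theta)


class _VaryingBlock:
    """Non-centered subject effects: u_s = z_s * sigma, z ~ N(0,1)."""

    def __init__(self, offset: int, q: int, subj: np.ndarray, Xv: np.ndarray,
                 shape: float, rate: float):
        self.offset, self.q = offset, q
        self.subj, self.Xv = subj, Xv
        self.n_subj = int(subj.max()) + 1 if len(subj) else 0
        self.shape, self.rate = shape, rate
        self.size = q + self.n_subj * q   # log-sigmas then z matrix
        onehot = np.zeros((len(subj), self.n_subj))
        onehot[np.arange(len(subj)), subj] = 1.0
        self.onehot_t = onehot.T.copy()   # (S, n)

    def eta(self, theta):
        """Returns (eta_v, ctx); ctx carries intermediates for grad/prior."""
        w = theta.shape[0]
        log_sig = theta[:, self.offset : self.offset + self.q]
        z = theta[:, self.offset + self.q : self.offset + self.size]
        z = z.reshape(w, self.n_subj, self.q)
        sig = np.exp(log_sig)
        z_sub = z[:, self.subj, :]                              # (W, n, q)
        eta_v = ((z_sub * self.Xv) @ sig[..., None])[:, :, 0]
        return eta_v, (z, z_sub, log_sig, sig)

    def log_prior(self, ctx):
        z, _, log_sig, sig = ctx
        return (_normal_logpdf(z, 1.0).sum(axis=(1, 2))
                + (self.shape * log_sig - self.rate * sig).sum(axis=1))

    def add_grad(self, grad, g, ctx):
        """Accumulate d(ll)/d(z, log_sigma) given g = d(ll)/d(eta) (W, n)."""
        z, z_sub, _, sig = ctx
        t = g[:, :, None] * self.Xv[None, :, :]                 # (W, n, q)
        dz = np.matmul(self.onehot_t, t) * sig[:, None, :]      # (W, S, q)
        dz -= z                                                 # z prior
        dls = sig * (t * z_sub).sum(axis=1)
        dls += self.shape - self.rate * sig                     # gamma prior
        grad[:, self.offset : self.offset + self.q] += dls
        grad[:, self.offset + self.q : self.offset + self.size] += \
            dz.reshape(z.shape[0], -1)


def beta_ispc_model(
    rows: pd.DataFrame, spec: ModelSpec | None = None
) -> LogPosterior:
    """Beta-likelihood, logit-link model for ISPC responses.

    Design: intercept + pleasantness (most = 1) + familiarity (old = 1)
    + interaction, reference level new/least; subject-varying counterpart of
    every term.  Responses must already be compressed inside (0, 1).
    Parameter layout: [beta(4) | log sigma_u(q) | z(S*q) | log phi].
    """
    spec = spec or ModelSpec("beta-logit")
    pr = spec.priors
    y = rows["ispc"].to_numpy(dtype=float)
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise ValueError(
            "ISPC responses touch the unit-interval boundary; apply "
            "adjust_unit_interval before fitting"
        )
    pleasant = (rows["pleasantness_class"].astype(str) == "most").to_numpy(float)
    old = (rows["familiarity_condition"].astype(str) == "old").to_numpy(float)
    X = np.column_stack([np.ones_like(y), pleasant, old, pleasant * old])
    subj, _ = _subject_codes(rows["subject"])
    Xv = X if spec.varying_slopes else X[:, :1]
    p, q = X.shape[1], Xv.shape[1]
    vb = _VaryingBlock(p, q, subj, Xv, pr.varying_shape, pr.varying_rate)
    ndim = p + vb.size + 1
    log_y, log_1my = np.log(y), np.log1p(-y)
    logit_y = log_y - log_1my

    n = len(y)
    sum_log1my = float(log_1my.sum())
    XT = X.T.copy()

    def logp_grad(theta, want_grad):
        beta = theta[:, :p]
        eta_v, ctx = vb.eta(theta)
        log_phi = theta[:, -1]
        phi1 = np.exp(log_phi)
        phi = phi1[:, None]
        mu = expit(beta @ XT + eta_v)
        mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
        a, b = mu * phi, (1.0 - mu) * phi
        # sum_i lgam(a+b) = n lgam(phi); (a-1)ln y + (b-1)ln(1-y) regrouped
        ll = (n * gammaln(phi1)
              + phi1 * (mu @ logit_y + sum_log1my)
              - (gammaln(a) + gammaln(b)).sum(axis=1)
              - float(log_y.sum()) - sum_log1my)
        lp = ll + _normal_logpdf(beta, pr.coef_sd).sum(axis=1)
        lp += vb.log_prior(ctx)
        lp += pr.phi_shape * log_phi - pr.phi_rate * phi1
        if not want_grad:
            return lp, None
        psi_a, psi_b = digamma(a), digamma(b)
        g = phi * mu * (1.0 - mu) * (psi_b - psi_a + logit_y)    # d ll / d eta
        grad = np.zeros_like(theta)
        grad[:, :p] = g @ X - beta / pr.coef_sd**2
        vb.add_grad(grad, g, ctx)
        dphi = (n * digamma(phi1) - (mu * (psi_a - logit_y)).sum(axis=1)
                - ((1.0 - mu) * psi_b).sum(axis=1) + sum_log1my)
        grad[:, -1] = phi1 * dphi + pr.phi_shape - pr.phi_rate * phi1
        return lp, grad

    names = ["beta0", "beta1", "beta2", "beta3"]
    monitored = {nm: (lambda t, j=j: t[:, j]) for j, nm in enumerate(names)}
    monitored["phi"] = lambda t: np.exp(t[:, -1])
    for k in range(q):
        monitored[f"sigma_u{k}"] = lambda t, k=k: np.exp(t[:, p + k])

    fast = None
    pack = None
    from . import _kernels as _k

    if _k.HAVE_NUMBA:
        subj_i = subj.astype(np.int64)
        n_subj = vb.n_subj

        def fast(th):
            return _k._beta_kernel(
                th, X, Xv, subj_i, n_subj, log_y, log_1my, logit_y,
                pr.coef_sd, pr.varying_shape, pr.varying_rate,
                pr.phi_shape, pr.phi_rate, True,
            )

        pack = (0, X, Xv, subj_i, log_y, log_1my, logit_y,
                np.empty(0, np.int64), _hyper_vector(pr, 0, n_subj))

    return LogPosterior(ndim, logp_grad, monitored, len(y), fast=fast,
                        numba_pack=pack)


def student_t_pleasantness_model(
    trial_table: pd.DataFrame, spec: ModelSpec | None = None
) -> LogPosterior:
    """Student-t linear model for time-weighted pleasantness (old vs new).

    Identity link; reference condition new, so beta1 is the old - new
    difference.  Only retained trials enter.  Parameter layout:
    [beta(2) | log sigma_u(q) | z(S*q) | log s | log nu].
    """
    spec = spec or ModelSpec("student-t")
    pr = spec.priors
    rows = trial_table[trial_table["retained"]] if "retained" in trial_table else trial_table
    y = rows["pleasantness_index"].to_numpy(dtype=float)
    cond = rows["familiarity_condition"].astype(str)
    if cond.nunique() < 2:
        raise ValueError("pleasantness model needs both new and old conditions")
    old = (cond == "old").to_numpy(float)
    X = np.column_stack([np.ones_like(y), old])
    subj, _ = _subject_codes(rows["subject"])
    Xv = X if spec.varying_slopes else X[:, :1]
    p, q = X.shape[1], Xv.shape[1]
    vb = _VaryingBlock(p, q, subj, Xv, pr.varying_shape, pr.varying_rate)
    ndim = p + vb.size + 2
    df_r, sc_r = pr.resid_df, pr.resid_scale

    def logp_grad(theta, want_grad):
        beta = theta[:, :p]
        eta_v, ctx = vb.eta(theta)
        log_s, log_nu = theta[:, -2], theta[:, -1]
        s = np.exp(log_s)[:, None]
        nu = np.exp(log_nu)[:, None]
        mu = beta @ X.T + eta_v
        r = (y[None, :] - mu) / s
        A = 1.0 + r * r / nu
        ll = (gammaln((nu + 1) / 2) - gammaln(nu / 2)
              - 0.5 * np.log(nu * np.pi) - np.log(s)
              - (nu + 1) / 2 * np.log(A)).sum(axis=1)
        lp = ll + _normal_logpdf(beta, pr.coef_sd).sum(axis=1)
        lp += vb.log_prior(ctx)
        sv = s[:, 0]
        lp += (gammaln((df_r + 1) / 2) - gammaln(df_r / 2)
               - 0.5 * np.log(df_r * np.pi) - np.log(sc_r)
               - (df_r + 1) / 2 * np.log1p((sv / sc_r) ** 2 / df_r)
               + np.log(2.0) + log_s)
        lp += _gamma_logpdf_log(log_nu, pr.nu_shape, pr.nu_rate)
        if not want_grad:
            return lp, None
        denom = nu + r * r
        g = (nu + 1) * r / (s * denom)                           # d ll / d mu
        grad = np.zeros_like(theta)
        grad[:, :p] = g @ X - beta / pr.coef_sd**2
        vb.add_grad(grad, g, ctx)
        dls = (-1.0 + (nu + 1) * r * r / denom).sum(axis=1)
        dls += 1.0 - (df_r + 1) * sv**2 / (df_r * sc_r**2 + sv**2)
        grad[:, -2] = dls
        dnu = (0.5 * digamma((nu + 1) / 2) - 0.5 * digamma(nu / 2)
               - 0.5 / nu - 0.5 * np.log(A)
               + (nu + 1) * r * r / (2 * nu * denom)).sum(axis=1)
        grad[:, -1] = nu[:, 0] * dnu + pr.nu_shape - pr.nu_rate * nu[:, 0]
        return lp, grad

    monitored = {
        "beta0": lambda t: t[:, 0],
        "beta1": lambda t: t[:, 1],
        "sigma": lambda t: np.exp(t[:, -2]),
        "nu": lambda t: np.exp(t[:, -1]),
    }
    for k in range(q):
        monitored[f"sigma_u{k}"] = lambda t, k=k: np.exp(t[:, p + k])

    fast = None
    pack = None
    from . import _kernels as _k

    if _k.HAVE_NUMBA:
        subj_i = subj.astype(np.int64)
        n_subj = vb.n_subj

        def fast(th):
            return _k._student_kernel(
                th, X, Xv, subj_i, n_subj, y,
                pr.coef_sd, pr.varying_shape, pr.varying_rate,
                pr.resid_scale, pr.resid_df, pr.nu_shape, pr.nu_rate, True,
            )

        pack = (1, X, Xv, subj_i, y, np.empty(0), np.empty(0),
                np.empty(0, np.int64), _hyper_vector(pr, 0, n_subj))

    return LogPosterior(ndim, logp_grad, monitored, len(y), fast=fast,
                        numba_pack=pack)


def ordinal_familiarity_model(
    ratings: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_categories: int = 7,
) -> LogPosterior:
    """Cumulative-probit multilevel model for 7-point familiarity ratings.

    The latent variable is normal with unit sd; six ordered thresholds carve
    it into the seven categories.  ``ratings`` needs columns ``subject``,
    ``rating`` (1..7) and ``condition`` in {"old", "exposure", "new"} with
    "old" (target music in the experimental session) as reference:
    beta1 = exposure - old, beta2 = new - old, both in latent-sd units.
    Thresholds are parameterized as first threshold plus log-increments so
    every draw respects the ordering.  Parameter layout:
    [beta(2) | c1, log-increments(n_thresh - 1) | log sigma_u(q) | z(S*q)].
    """
    spec = spec or ModelSpec("cumulative-probit")
    pr = spec.priors
    yk = ratings["rating"].to_numpy(dtype=int)
    if np.any((yk < 1) | (yk > n_categories)):
        raise ValueError(f"ratings outside 1..{n_categories}")
    cond = ratings["condition"].astype(str)
    bad = set(cond.unique()) - {"old", "exposure", "new"}
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}")
    expo = (cond == "exposure").to_numpy(float)
    new = (cond == "new").to_numpy(float)
    X = np.column_stack([expo, new])                 # no intercept: thresholds absorb it
    subj, _ = _subject_codes(ratings["subject"])
    Xv = np.column_stack([np.ones_like(expo), expo, new]) if spec.varying_slopes \
        else np.ones((len(expo), 1))
    p, q = 2, Xv.shape[1]
    n_thresh = n_categories - 1
    vb = _VaryingBlock(p + n_thresh, q, subj, Xv, pr.varying_shape, pr.varying_rate)
    ndim = p + n_thresh + vb.size
    n = len(yk)
    # indicator matrices: which threshold is each observation's upper/lower bound
    upper_ind = np.zeros((n, n_thresh))
    lower_ind = np.zeros((n, n_thresh))
    upper_ind[yk <= n_thresh, yk[yk <= n_thresh] - 1] = 1.0
    lower_ind[yk >= 2, yk[yk >= 2] - 2] = 1.0

    def thresholds(theta):
        c1 = theta[:, p : p + 1]
        deltas = np.exp(theta[:, p + 1 : p + n_thresh])
        return np.concatenate([c1, c1 + np.cumsum(deltas, axis=1)], axis=1)

    def logp_grad(theta, want_grad):
        beta = theta[:, :p]
        c = thresholds(theta)                        # (W, n_thresh), ordered
        w = theta.shape[0]
        eta_v, ctx = vb.eta(theta)
        eta = beta @ X.T + eta_v
        cmat = np.concatenate(
            [np.full((w, 1), -np.inf), c, np.full((w, 1), np.inf)], axis=1
        )
        upper = cmat[:, yk] - eta
        lower = cmat[:, yk - 1] - eta
        prob = np.clip(ndtr(upper) - ndtr(lower), 1e-300, None)
        ll = np.log(prob).sum(axis=1)
        lp = ll + _normal_logpdf(beta, pr.coef_sd).sum(axis=1)
        lp += _normal_logpdf(c, pr.coef_sd).sum(axis=1)       # prior on thresholds
        lp += theta[:, p + 1 : p + n_thresh].sum(axis=1)      # Jacobian of increments
        lp += vb.log_prior(ctx)
        if not want_grad:
            return lp, None
        with np.errstate(invalid="ignore"):
            pdf_u = np.where(np.isfinite(upper),
                             np.exp(-0.5 * np.where(np.isfinite(upper), upper, 0.0) ** 2)
                             / _SQRT_2PI, 0.0)
            pdf_l = np.where(np.isfinite(lower),
                             np.exp(-0.5 * np.where(np.isfinite(lower), lower, 0.0) ** 2)
                             / _SQRT_2PI, 0.0)
        g = (pdf_l - pdf_u) / prob                   # d ll / d eta
        grad = np.zeros_like(theta)
        grad[:, :p] = g @ X - beta / pr.coef_sd**2
        vb.add_grad(grad, g, ctx)
        dC = (pdf_u / prob) @ upper_ind - (pdf_l / prob) @ lower_ind
        dC -= c / pr.coef_sd**2                      # threshold prior
        grad[:, p] = dC.sum(axis=1)                  # first threshold moves all
        # log-increment j shifts thresholds j..end; +1 is the Jacobian term
        rev_cum = np.cumsum(dC[:, ::-1], axis=1)[:, ::-1]
        deltas = np.exp(theta[:, p + 1 : p + n_thresh])
        grad[:, p + 1 : p + n_thresh] = deltas * rev_cum[:, 1:] + 1.0
        return lp, grad

    monitored = {
        "beta1": lambda t: t[:, 0],
        "beta2": lambda t: t[:, 1],
        "beta2_minus_beta1": lambda t: t[:, 1] - t[:, 0],
    }
    for j in range(n_thresh):
        monitored[f"threshold{j + 1}"] = lambda t, j=j: thresholds(t)[:, j]
    for k in range(q):
        monitored[f"sigma_u{k}"] = lambda t, k=k: np.exp(t[:, p + n_thresh + k])

    fast = None
    pack = None
    from . import _kernels as _k

    if _k.HAVE_NUMBA:
        subj_i = subj.astype(np.int64)
        yk_i = yk.astype(np.int64)
        n_subj = vb.n_subj

        def fast(th):
            return _k._ordinal_kernel(
                th, X, Xv, subj_i, n_subj, yk_i, n_thresh,
                pr.coef_sd, pr.varying_shape, pr.varying_rate, True,
            )

        pack = (2, X, Xv, subj_i, np.empty(0), np.empty(0), np.empty(0),
                yk_i, _hyper_vector(pr, n_thresh, n_subj))

    return LogPosterior(ndim, logp_grad, monitored, len(yk), fast=fast,
                        numba_pack=pack)
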