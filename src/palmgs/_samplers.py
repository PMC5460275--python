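"""Numba Gibbs-sampler kernels for the Bayesian whole-genome regressions.

Each kernel runs a full chain on a column-centered marker matrix and returns
posterior means (and per-marker posterior sd) computed from the post-burn-in
samples, plus the residual-variance chain for convergence diagnostics.
Marker-effect priors per method:

* BRR  -- one common effect variance, scaled-inverse-chi2 hyperprior.
* BA   -- marker-specific effect variances, scaled-inverse-chi2 prior.
* BC   -- spike-slab mixture: effect is 0 with probability pi (Beta(1,1)
          prior on pi) or drawn from a common-variance slab.
* BL   -- double-exponential prior via the Park-Casella scale mixture;
          lambda^2 carries a gamma prior and the residual variance update
          includes the u'D^-1 u term of the full hierarchy.

Residual and effect variances use scaled-inverse-chi2 updates implemented
as scale/chi2 draws.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["gibbs_brr", "gibbs_ba", "gibbs_bc", "gibbs_bl"]


@njit(cache=True, fastmath=True)
def _dot(a, b):
    s = 0.0
    for i in range(a.shape[0]):
        s += a[i] * b[i]
    return s


@njit(cache=True, fastmath=True)
def _update_residual(e, x, delta_u):
    for i in range(e.shape[0]):
        e[i] += x[i] * delta_u


@njit(cache=True)
def _sample_mu(e, mu, s2e):
    n = e.shape[0]
    mean = 0.0
    for i in range(n):
        mean += e[i]
    mean = mean / n + mu
    mu_new = np.random.normal(mean, np.sqrt(s2e / n))
    for i in range(n):
        e[i] += mu - mu_new
    return mu_new


@njit(cache=True)
def _inv_gauss(mu, lam):
    """One inverse-Gaussian draw (Michael-Schucany-Haas)."""
    nu = np.random.normal(0.0, 1.0)
    z = nu * nu
    x = mu + mu * mu * z / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * z + mu * mu * z * z
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def gibbs_brr(M, y, n_iter, burn_in, thin, df_u, s_u, df_e, s_e, seed):
    np.random.seed(seed)
    n, m = M.shape
    mu = y.mean()
    u = np.zeros(m)
    e = y - mu
    xtx = np.empty(m)
    for j in range(m):
        xtx[j] = _dot(M[:, j], M[:, j])
    s2u = s_u
    s2e = s_e

    n_kept = 0
    mu_sum = 0.0
    u_sum = np.zeros(m)
    u_sq = np.zeros(m)
    s2u_sum = 0.0
    s2e_sum = 0.0
    chain = np.empty((n_iter - burn_in) // thin + 1)
    c_idx = 0

    for it in range(n_iter):
        mu = _sample_mu(e, mu, s2e)
        lam = s2e / s2u
        for j in range(m):
            if xtx[j] <= 0.0:
                continue
            x = M[:, j]
            rhs = _dot(x, e) + xtx[j] * u[j]
            c = xtx[j] + lam
            unew = rhs / c + np.random.normal(0.0, 1.0) * np.sqrt(s2e / c)
            _update_residual(e, x, u[j] - unew)
            u[j] = unew
        s2u = (s_u * df_u + _dot(u, u)) / np.random.chisquare(df_u + m)
        s2e = (s_e * df_e + _dot(e, e)) / np.random.chisquare(df_e + n)
        if not np.isfinite(s2e) or s2e <= 0.0:
            raise ValueError("residual variance diverged during sampling")
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_kept += 1
            mu_sum += mu
            for j in range(m):
                u_sum[j] += u[j]
                u_sq[j] += u[j] * u[j]
            s2u_sum += s2u
            s2e_sum += s2e
            chain[c_idx] = s2e
            c_idx += 1

    return (
        mu_sum / n_kept,
        u_sum / n_kept,
        u_sq / n_kept,
        s2u_sum / n_kept,
        s2e_sum / n_kept,
        0.0,
        chain[:c_idx],
    )


@njit(cache=True)
def gibbs_ba(M, y, n_iter, burn_in, thin, df_u, s_u, df_e, s_e, seed):
    np.random.seed(seed)
    n, m = M.shape
    mu = y.mean()
    u = np.zeros(m)
    e = y - mu
    xtx = np.empty(m)
    for j in range(m):
        xtx[j] = _dot(M[:, j], M[:, j])
    s2j = np.full(m, s_u)
    s2e = s_e

    n_kept = 0
    mu_sum = 0.0
    u_sum = np.zeros(m)
    u_sq = np.zeros(m)
    s2u_sum = 0.0
    s2e_sum = 0.0
    chain = np.empty((n_iter - burn_in) // thin + 1)
    c_idx = 0

    for it in range(n_iter):
        mu = _sample_mu(e, mu, s2e)
        for j in range(m):
            if xtx[j] <= 0.0:
                continue
            x = M[:, j]
            rhs = _dot(x, e) + xtx[j] * u[j]
            c = xtx[j] + s2e / s2j[j]
            unew = rhs / c + np.random.normal(0.0, 1.0) * np.sqrt(s2e / c)
            _update_residual(e, x, u[j] - unew)
            u[j] = unew
            s2j[j] = (s_u * df_u + u[j] * u[j]) / np.random.chisquare(df_u + 1.0)
        s2e = (s_e * df_e + _dot(e, e)) / np.random.chisquare(df_e + n)
        if not np.isfinite(s2e) or s2e <= 0.0:
            raise ValueError("residual variance diverged during sampling")
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_kept += 1
            mu_sum += mu
            for j in range(m):
                u_sum[j] += u[j]
                u_sq[j] += u[j] * u[j]
            s2u_sum += s2j.mean()
            s2e_sum += s2e
            chain[c_idx] = s2e
            c_idx += 1

    return (
        mu_sum / n_kept,
        u_sum / n_kept,
        u_sq / n_kept,
        s2u_sum / n_kept,
        s2e_sum / n_kept,
        0.0,
        chain[:c_idx],
    )


@njit(cache=True)
def gibbs_bc(M, y, n_iter, burn_in, thin, df_u, s_u, df_e, s_e, pi_init, seed):
    np.random.seed(seed)
    n, m = M.shape
    mu = y.mean()
    u = np.zeros(m)
    incl = np.zeros(m, dtype=np.bool_)
    e = y - mu
    xtx = np.empty(m)
    for j in range(m):
        xtx[j] = _dot(M[:, j], M[:, j])
    s2u = s_u
    s2e = s_e
    pi = pi_init  # probability a marker is EXCLUDED

    n_kept = 0
    mu_sum = 0.0
    u_sum = np.zeros(m)
    u_sq = np.zeros(m)
    s2u_sum = 0.0
    s2e_sum = 0.0
    pi_sum = 0.0
    chain = np.empty((n_iter - burn_in) // thin + 1)
    c_idx = 0

    for it in range(n_iter):
        mu = _sample_mu(e, mu, s2e)
        k_in = 0
        ss_in = 0.0
        for j in range(m):
            if xtx[j] <= 0.0:
                continue
            x = M[:, j]
            old = u[j] if incl[j] else 0.0
            r = _dot(x, e) + xtx[j] * old
            v0 = xtx[j] * s2e
            v1 = v0 + xtx[j] * xtx[j] * s2u
            log_bf = 0.5 * (np.log(v0 / v1) + r * r * (1.0 / v0 - 1.0 / v1))
            logit = log_bf + np.log((1.0 - pi) / pi)
            if logit > 35.0:
                p_in = 1.0
            elif logit < -35.0:
                p_in = 0.0
            else:
                p_in = 1.0 / (1.0 + np.exp(-logit))
            if np.random.random() < p_in:
                c = xtx[j] + s2e / s2u
                unew = r / c + np.random.normal(0.0, 1.0) * np.sqrt(s2e / c)
                incl[j] = True
                k_in += 1
                ss_in += unew * unew
            else:
                unew = 0.0
                incl[j] = False
            _update_residual(e, x, old - unew)
            u[j] = unew
        pi = np.random.beta(1.0 + m - k_in, 1.0 + k_in)
        if pi < 1e-6:
            pi = 1e-6
        if pi > 1.0 - 1e-6:
            pi = 1.0 - 1e-6
        s2u = (s_u * df_u + ss_in) / np.random.chisquare(df_u + k_in)
        s2e = (s_e * df_e + _dot(e, e)) / np.random.chisquare(df_e + n)
        if not np.isfinite(s2e) or s2e <= 0.0:
            raise ValueError("residual variance diverged during sampling")
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_kept += 1
            mu_sum += mu
            for j in range(m):
                u_sum[j] += u[j]
                u_sq[j] += u[j] * u[j]
            s2u_sum += s2u
            s2e_sum += s2e
            pi_sum += pi
            chain[c_idx] = s2e
            c_idx += 1

    return (
        mu_sum / n_kept,
        u_sum / n_kept,
        u_sq / n_kept,
        s2u_sum / n_kept,
        s2e_sum / n_kept,
        pi_sum / n_kept,
        chain[:c_idx],
    )


@njit(cache=True)
def gibbs_bl(
    M, y, n_iter, burn_in, thin, df_e, s_e, lambda_init, lambda_shape, lambda_rate, seed
):
    np.random.seed(seed)
    n, m = M.shape
    mu = y.mean()
    u = np.zeros(m)
    e = y - mu
    xtx = np.empty(m)
    for j in range(m):
        xtx[j] = _dot(M[:, j], M[:, j])
    lam2 = lambda_init * lambda_init
    tau2 = np.full(m, 1.0 / lam2)
    s2e = s_e

    n_kept = 0
    mu_sum = 0.0
    u_sum = np.zeros(m)
    u_sq = np.zeros(m)
    s2u_sum = 0.0
    s2e_sum = 0.0
    lam_sum = 0.0
    chain = np.empty((n_iter - burn_in) // thin + 1)
    c_idx = 0

    for it in range(n_iter):
        mu = _sample_mu(e, mu, s2e)
        for j in range(m):
            if xtx[j] <= 0.0:
                continue
            x = M[:, j]
            rhs = _dot(x, e) + xtx[j] * u[j]
            c = xtx[j] + 1.0 / tau2[j]
            unew = rhs / c + np.random.normal(0.0, 1.0) * np.sqrt(s2e / c)
            _update_residual(e, x, u[j] - unew)
            u[j] = unew
        # scale-mixture latent variances
        sum_tau2 = 0.0
        uDu = 0.0
        for j in range(m):
            u2 = u[j] * u[j]
            if u2 < 1e-12 * s2e:
                u2 = 1e-12 * s2e
            mu_ig = np.sqrt(lam2 * s2e / u2)
            inv_tau2 = _inv_gauss(mu_ig, lam2)
            tau2[j] = 1.0 / inv_tau2
            sum_tau2 += tau2[j]
            uDu += u[j] * u[j] * inv_tau2
        lam2 = np.random.gamma(lambda_shape + m, 1.0 / (lambda_rate + 0.5 * sum_tau2))
        s2e = (s_e * df_e + _dot(e, e) + uDu) / np.random.chisquare(df_e + n + m)
        if not np.isfinite(s2e) or s2e <= 0.0:
            raise ValueError("residual variance diverged during sampling")
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_kept += 1
            mu_sum += mu
            for j in range(m):
                u_sum[j] += u[j]
                u_sq[j] += u[j] * u[j]
            s2u_sum += s2e * sum_tau2 / m
            s2e_sum += s2e
            lam_sum += np.sqrt(lam2)
            chain[c_idx] = s2e
            c_idx += 1

    return (
        mu_sum / n_kept,
        u_sum / n_kept,
        u_sq / n_kept,
        s2u_sum / n_kept,
        s2e_sum / n_kept,
        lam_sum / n_kept,
        chain[:c_idx],
    )
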