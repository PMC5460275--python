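"""Restricted maximum likelihood for the one-variance-component model.

Model: y = X beta + g + e with g ~ N(0, K sigma2_g), e ~ N(0, I sigma2_e).
The REML log-likelihood is profiled down to a one-dimensional search over
the variance ratio delta = sigma2_e / sigma2_g on the eigenspectrum of the
projected relationship matrix, following the standard spectral trick: with
S the residual-forming projection of X and S K S = U diag(xi) U', the
rotated data eta = U'y are independent with variances sigma2_g (xi + delta),
so the criterion is

    f(delta) = (n - p) log( sum eta_i^2 / (xi_i + delta) )
             + sum log(xi_i + delta)

minimized over log(delta) with a bounded scalar search (tolerance 1e-8).
When K = Mc Mc' for a centered n x m marker matrix with m < n, the non-zero
eigenpairs are obtained from the small m x m cross-product instead, with the
zero-eigenvalue mass folded in analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["REMLResult", "reml_from_K", "reml_from_markers"]

_LOG_DELTA_BOUNDS = (-23.0, 28.0)  # delta in ~[1e-10, 1.4e12]
_EIG_TOL = 1e-9


@dataclass
class REMLResult:
    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray  # GLS fixed effects
    delta: float  # sigma2_e / sigma2_g


def _profile(xi, eta2, n_eff, tail_ss, tail_count):
    """Minimize the profiled REML criterion over log(delta)."""

    def crit(log_delta: float) -> float:
        delta = np.exp(log_delta)
        quad = float(np.sum(eta2 / (xi + delta)))
        if tail_count > 0:
            quad += tail_ss / delta
        quad = max(quad, 1e-300)
        logdet = float(np.sum(np.log(xi + delta))) + tail_count * log_delta
        return n_eff * np.log(quad) + logdet

    res = minimize_scalar(
        crit,
        bounds=_LOG_DELTA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    quad = float(np.sum(eta2 / (xi + delta)))
    if tail_count > 0:
        quad += tail_ss / delta
    sigma2_g = quad / n_eff
    sigma2_e = delta * sigma2_g
    return sigma2_g, sigma2_e, delta


def reml_from_K(K: np.ndarray, y: np.ndarray, X: np.ndarray | None = None) -> REMLResult:
    """REML variance components for an arbitrary (PSD) relationship matrix."""
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    p = X.shape[1]
    if np.var(y) == 0.0:
        raise ValueError("response has zero variance")

    XtX_inv = np.linalg.pinv(X.T @ X)
    P = np.eye(n) - X @ XtX_inv @ X.T
    SKS = P @ K @ P
    SKS = (SKS + SKS.T) / 2.0
    w, U = np.linalg.eigh(SKS)
    # keep only clearly positive eigenpairs: eigh's null-space basis mixes
    # span(X) with the residual null space, so the zero-eigenvalue mass is
    # folded in analytically via y'Py - sum(eta^2) instead
    pos = w > max(w.max(), 1.0) * _EIG_TOL
    xi = w[pos]
    eta = U[:, pos].T @ y
    Py = P @ y
    tail_ss = max(float(Py @ Py) - float(eta @ eta), 0.0)
    n_eff = n - p
    tail_count = n_eff - int(pos.sum())
    if tail_count <= 0:
        tail_count, tail_ss = 0, 0.0
    sigma2_g, sigma2_e, delta = _profile(xi, eta**2, n_eff, tail_ss, tail_count)

    V = sigma2_g * K + sigma2_e * np.eye(n)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vinv_X, X.T @ Vinv_y)
    return REMLResult(sigma2_g, sigma2_e, beta, delta)


def reml_from_markers(Mc: np.ndarray, y: np.ndarray) -> REMLResult:
    """REML for K = Mc Mc' with column-centered markers and intercept only.

    Exploits the fact that for column-centered Mc the intercept projection
    commutes with K (Mc'1 = 0), so the GLS intercept is exactly mean(y) and
    the non-zero eigenvalues of the projected K are those of Mc'Mc.
    """
    y = np.asarray(y, dtype=np.float64)
    n, m = Mc.shape
    if np.var(y) == 0.0:
        raise ValueError("response has zero variance")
    yc = y - y.mean()
    if m >= n:
        return reml_from_K(Mc @ Mc.T, y)

    A = Mc.T @ Mc
    A = (A + A.T) / 2.0
    w, W = np.linalg.eigh(A)
    keep = w > max(w.max(), 1.0) * _EIG_TOL
    xi = w[keep]
    # eigenvectors of Mc Mc' with non-zero eigenvalue: Mc W / sqrt(xi)
    proj = (Mc @ W[:, keep]) / np.sqrt(xi)
    eta = proj.T @ yc
    ss_total = float(yc @ yc)
    tail_ss = max(ss_total - float(eta @ eta), 0.0)
    rank = int(keep.sum())
    n_eff = n - 1
    sigma2_g, sigma2_e, delta = _profile(xi, eta**2, n_eff, tail_ss, n_eff - rank)
    return REMLResult(sigma2_g, sigma2_e, np.array([y.mean()]), delta)
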