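"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed forms implemented in the package:
the changepoint posterior is integrated numerically in 2-D over
(sigma0, delta); the H0 supremum is found by grid search plus bounded
1-D refinement; the variance-ratio posterior moments and marginal CDF
come from nested quadrature of the full posterior.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, optimize


def _log_integrand_uv(u, v, t, n, s1, s2):
    """Log of L(t, sigma0, delta) * (1/sigma0) in log coordinates
    u = log sigma0, v = log delta, including the du dv Jacobian."""
    n2 = n - t
    try:
        return (
            -n * u
            + (1.0 - n2 / 2.0) * v
            - 0.5 * s1 * math.exp(-2.0 * u)
            - 0.5 * s2 * math.exp(-2.0 * u - v)
        )
    except OverflowError:
        return -math.inf


def changepoint_log_marginal(y: np.ndarray, t: int) -> float:
    """log of the 2-D integral of the likelihood x uniform(delta) x Jeffreys(sigma0)
    at candidate cut t (left = y[:t]).  Constant convention: the
    (2*pi)^(-N/2) likelihood factor is dropped (it is t-independent)."""
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    s1 = float(np.sum(y[:t] ** 2))
    s2 = float(np.sum(y[t:] ** 2))

    # locate the mode in (u, v) to factor out the peak value
    res = optimize.minimize(
        lambda p: -_log_integrand_uv(p[0], p[1], t, n, s1, s2),
        x0=[0.5 * math.log(s1 / t), math.log((s2 / (n - t)) / (s1 / t))],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
    )
    m = -res.fun

    def inner(v):
        val, _ = integrate.quad(
            lambda u: math.exp(_log_integrand_uv(u, v, t, n, s1, s2) - m),
            -np.inf,
            np.inf,
            epsabs=1e-13,
            epsrel=1e-11,
            limit=200,
        )
        return val

    total, _ = integrate.quad(inner, -np.inf, np.inf, epsabs=1e-13, epsrel=1e-11, limit=200)
    return m + math.log(total)


def changepoint_posterior_quadrature(y: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Normalised posterior over `support` (uniform prior on t) by 2-D quadrature."""
    logs = np.array([changepoint_log_marginal(y, int(t)) for t in support])
    w = np.exp(logs - logs.max())
    return w / w.sum()


# ---------------------------------------------------------------------------
# FBST oracles


def _log_post_uv(u, v, n1, n2, ss1, ss2, beta):
    """Full (sigma0, delta) log posterior in log coordinates with Jacobian."""
    try:
        s2 = math.exp(2.0 * u)
        d = math.exp(v)
        return (
            -abs(d - 1.0) / beta
            - (n1 + n2 + 1) * u
            - (n2 / 2.0) * v
            - 0.5 * ss1 / s2
            - 0.5 * ss2 / (d * s2)
            + u
            + v
        )
    except (OverflowError, ZeroDivisionError):
        return -math.inf


def _fbst_integral(n1, n2, ss1, ss2, beta, f=None):
    """Integral of f(sigma0, delta) * posterior kernel over the plane."""
    u0 = 0.5 * math.log((ss1 + ss2) / (n1 + n2))
    v0 = math.log((ss2 / n2) / (ss1 / n1))
    res = optimize.minimize(
        lambda p: -_log_post_uv(p[0], p[1], n1, n2, ss1, ss2, beta),
        x0=[u0, v0],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
    )
    m = -res.fun

    def inner(v):
        def g(u):
            w = math.exp(_log_post_uv(u, v, n1, n2, ss1, ss2, beta) - m)
            return w if f is None else w * f(math.exp(u), math.exp(v))

        val, _ = integrate.quad(g, -np.inf, np.inf, epsabs=1e-13, epsrel=1e-10, limit=200)
        return val

    val, _ = integrate.quad(inner, -np.inf, np.inf, epsabs=1e-13, epsrel=1e-10, limit=200)
    return m + math.log(val)  # log of the integral


def fbst_posterior_mean_delta(n1, n2, ss1, ss2, beta) -> float:
    log_norm = _fbst_integral(n1, n2, ss1, ss2, beta)
    log_num = _fbst_integral(n1, n2, ss1, ss2, beta, f=lambda s, d: d)
    return math.exp(log_num - log_norm)


def fbst_delta_marginal_cdf(n1, n2, ss1, ss2, beta, d_grid: np.ndarray) -> np.ndarray:
    """Marginal CDF of delta on d_grid via sigma0-quadrature + trapezoid."""
    dense = np.linspace(min(d_grid.min() * 0.5, 1e-3), d_grid.max() * 1.5, 2000)
    log_dens = np.empty(dense.size)
    for i, d in enumerate(dense):
        v = math.log(d)

        def g(u):
            return math.exp(_log_post_uv(u, v, n1, n2, ss1, ss2, beta))

        # peak over u at fixed d: sigma0^2 ~ (ss1 + ss2/d)/(n1+n2+1)
        u0 = 0.5 * math.log((ss1 + ss2 / d) / (n1 + n2 + 1))
        m = _log_post_uv(u0, v, n1, n2, ss1, ss2, beta)
        val, _ = integrate.quad(
            lambda u: math.exp(_log_post_uv(u, v, n1, n2, ss1, ss2, beta) - m),
            -np.inf,
            np.inf,
            epsabs=1e-13,
            epsrel=1e-9,
            limit=200,
        )
        # density of v = log d; includes the Jacobian already
        log_dens[i] = m + math.log(val)

    dens = np.exp(log_dens - log_dens.max())
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(np.log(dense)))])
    cdf /= cdf[-1]
    return np.interp(np.log(d_grid), np.log(dense), cdf)


def sup_h0_grid_search(n1, n2, ss1, ss2, beta, log_post) -> float:
    """Max over sigma0 at delta = 1 by log-spaced grid + bounded refinement."""
    pooled = math.sqrt((ss1 + ss2) / (n1 + n2))
    grid = np.geomspace(1e-3 * pooled, 1e3 * pooled, 4001)
    vals = [log_post(s, 1.0) for s in grid]
    i = int(np.argmax(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda s: -log_post(s, 1.0), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-14},
    )
    return -res.fun
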