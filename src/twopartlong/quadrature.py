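r"""Gauss-Hermite quadrature for random-effect integrals.

All marginal likelihoods in this package are integrals of a conditional
likelihood against a (possibly correlated) Gaussian random-effect density, or
against a positive frailty density.  The routines here evaluate

    log \int exp(f(u)) N(u; m, s^2) du          (1-D)
    log \int\int exp(f(u, v)) N((u,v); 0, C) du dv   (2-D)

by Gauss-Hermite product rules, optionally recentred and rescaled at the
per-subject posterior mode ("adaptive" quadrature, the standard device for
mixed-model likelihoods).  A vectorised engine evaluates the integral for all
subjects of a panel simultaneously, which is what the model fits use.

Conventions: probabilists' Hermite nodes/weights, with weights normalised to
sum to one, so a rule integrates exactly against the standard normal density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import roots_hermitenorm

__all__ = [
    "QuadratureRule",
    "gauss_hermite_rule",
    "integrate_re_1d",
    "integrate_re_2d",
    "adaptive_center",
    "log_marginal_subjects_2d",
    "log_marginal_subjects_1d",
    "logsumexp",
]

_LOG_REALMIN = np.log(np.finfo(float).tiny)


def logsumexp(a, axis=None):
    """log(sum(exp(a))) with the usual max-shift; -inf slices stay -inf."""
    a = np.asarray(a, dtype=float)
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.sum(np.exp(a - m), axis=axis)) + np.squeeze(m, axis=axis)
    return out


@dataclass(frozen=True)
class QuadratureRule:
    """Nodes and normalised weights of a probabilists' Gauss-Hermite rule.

    ``sum(weights * g(nodes))`` approximates ``E[g(X)]`` for X ~ N(0, 1),
    exactly for polynomial g of degree up to 2*order - 1.
    """

    order: int
    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("quadrature order must be >= 1")


def gauss_hermite_rule(order: int) -> QuadratureRule:
    x, w = roots_hermitenorm(int(order))
    w = w / np.sqrt(2.0 * np.pi)
    return QuadratureRule(order=int(order), nodes=x, weights=w)


def _as_rule(rule) -> QuadratureRule:
    if isinstance(rule, QuadratureRule):
        return rule
    return gauss_hermite_rule(int(rule))


def integrate_re_1d(logf, mean: float, sd: float, rule=20) -> float:
    """log of the integral of exp(logf(u)) against N(mean, sd^2).

    ``logf`` may return -inf (zero-likelihood region); non-finite positive
    values are rejected.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    rule = _as_rule(rule)
    vals = np.asarray([logf(mean + sd * x) for x in rule.nodes], dtype=float)
    if np.any(np.isposinf(vals)) or np.any(np.isnan(vals)):
        raise FloatingPointError("log-integrand not bounded above on nodes")
    with np.errstate(divide="ignore"):
        logw = np.log(rule.weights)
    return float(logsumexp(logw + vals))


def integrate_re_2d(logf, cov, rule=20) -> float:
    """log of the integral of exp(logf(u, v)) against N(0, cov), cov 2x2.

    A singular (rank-1) covariance collapses to a 1-D integral along the
    degenerate direction, which supports perfectly correlated random-effect
    pairs (|rho| = 1).
    """
    rule = _as_rule(rule)
    cov = np.asarray(cov, dtype=float)
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    if det <= 1e-12 * max(cov[0, 0] * cov[1, 1], 1e-300):
        # degenerate: (u, v) = (s_u, +/- s_v) * a with a ~ N(0,1)
        su = np.sqrt(max(cov[0, 0], 0.0))
        sv = np.sqrt(max(cov[1, 1], 0.0))
        sgn = 1.0 if cov[0, 1] >= 0 else -1.0
        return integrate_re_1d(lambda a: logf(su * a, sgn * sv * a), 0.0, 1.0, rule)
    L = np.linalg.cholesky(cov)
    with np.errstate(divide="ignore"):
        logw = np.add.outer(np.log(rule.weights), np.log(rule.weights)).ravel()
    z1 = np.repeat(rule.nodes, rule.order)
    z2 = np.tile(rule.nodes, rule.order)
    u = L[0, 0] * z1
    v = L[1, 0] * z1 + L[1, 1] * z2
    vals = np.asarray([logf(ui, vi) for ui, vi in zip(u, v)], dtype=float)
    return float(logsumexp(logw + vals))


def _fd_mode_newton(h, dim, n, max_iter=25, step=1e-4, tol=1e-9):
    """Vectorised Newton mode search of h over R^dim for n subjects.

    ``h`` maps arrays of shape (n, m) per coordinate to (n, m) values.
    Gradient/Hessian by central finite differences.  Returns (mode, hess).
    """
    x = np.zeros((n, dim))
    d = step ** 0.5  # ~1e-2: curvature of log-likelihoods is smooth
    for _ in range(max_iter):
        if dim == 1:
            a = x[:, 0:1]
            f0 = h(a)
            fp = h(a + d)
            fm = h(a - d)
            g = (fp - fm) / (2 * d)
            H = (fp - 2 * f0 + fm) / d**2
            H = np.where(H < -1e-8, H, -1.0)
            delta = -g / H
            delta = np.clip(delta, -2.0, 2.0)
            x[:, 0] += delta[:, 0]
            if np.max(np.abs(delta)) < tol:
                break
        else:
            a, b = x[:, 0:1], x[:, 1:2]
            f0 = h(a, b)
            fpa, fma = h(a + d, b), h(a - d, b)
            fpb, fmb = h(a, b + d), h(a, b - d)
            fpp, fmm = h(a + d, b + d), h(a - d, b - d)
            fpm, fmp = h(a + d, b - d), h(a - d, b + d)
            ga = (fpa - fma) / (2 * d)
            gb = (fpb - fmb) / (2 * d)
            haa = (fpa - 2 * f0 + fma) / d**2
            hbb = (fpb - 2 * f0 + fmb) / d**2
            hab = (fpp + fmm - fpm - fmp) / (4 * d**2)
            # Newton step with a negative-definiteness guard
            det = haa * hbb - hab**2
            ok = (haa < -1e-8) & (det > 1e-12)
            haa = np.where(ok, haa, -1.0)
            hbb = np.where(ok, hbb, -1.0)
            hab = np.where(ok, hab, 0.0)
            det = haa * hbb - hab**2
            da = -(hbb * ga - hab * gb) / det
            db = -(haa * gb - hab * ga) / det
            da = np.clip(da, -2.0, 2.0)
            db = np.clip(db, -2.0, 2.0)
            x[:, 0] += da[:, 0]
            x[:, 1] += db[:, 0]
            if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
                break
    if dim == 1:
        a = x[:, 0:1]
        H = (h(a + d) - 2 * h(a) + h(a - d)) / d**2
        return x, H[:, 0]
    a, b = x[:, 0:1], x[:, 1:2]
    f0 = h(a, b)
    haa = (h(a + d, b) - 2 * f0 + h(a - d, b)) / d**2
    hbb = (h(a, b + d) - 2 * f0 + h(a, b - d)) / d**2
    hab = (h(a + d, b + d) + h(a - d, b - d) - h(a + d, b - d) - h(a - d, b + d)) / (
        4 * d**2
    )
    return x, np.stack([haa[:, 0], hab[:, 0], hbb[:, 0]], axis=1)


def log_marginal_subjects_2d(cond_loglik, n_subjects, cov, rule=20, adaptive=True):
    """Per-subject log marginal likelihood over a correlated Gaussian pair.

    ``cond_loglik(u, v)`` takes arrays of shape (n_subjects, m) of random
    effect values and returns the per-subject conditional log-likelihood sums,
    shape (n_subjects, m).  ``cov`` is the 2x2 random-effect covariance.

    Returns an array of length n_subjects.  With ``adaptive=True`` nodes are
    recentred at each subject's posterior mode and rescaled by the posterior
    curvature before the product rule is applied.
    """
    rule = _as_rule(rule)
    cov = np.asarray(cov, dtype=float)
    n = int(n_subjects)
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    if det <= 1e-12 * max(cov[0, 0] * cov[1, 1], 1e-300):
        su = np.sqrt(max(cov[0, 0], 0.0))
        sv = np.sqrt(max(cov[1, 1], 0.0))
        sgn = 1.0 if cov[0, 1] >= 0 else -1.0
        return log_marginal_subjects_1d(
            lambda a: cond_loglik(su * a, sgn * sv * a), n, rule=rule, adaptive=adaptive
        )
    L = np.linalg.cholesky(cov)

    def uv(a, b):
        return L[0, 0] * a, L[1, 0] * a + L[1, 1] * b

    with np.errstate(divide="ignore"):
        logw = np.add.outer(np.log(rule.weights), np.log(rule.weights)).ravel()
    z1 = np.repeat(rule.nodes, rule.order)[None, :]
    z2 = np.tile(rule.nodes, rule.order)[None, :]

    if not adaptive:
        u, v = uv(z1, z2)
        vals = cond_loglik(np.broadcast_to(u, (n, u.shape[1])),
                           np.broadcast_to(v, (n, v.shape[1])))
        return logsumexp(logw[None, :] + vals, axis=1)

    def h(a, b):
        u, v = uv(a, b)
        return cond_loglik(u, v) - 0.5 * (a**2 + b**2)

    mode, hess = _fd_mode_newton(h, 2, n)
    haa, hab, hbb = hess[:, 0], hess[:, 1], hess[:, 2]
    detH = haa * hbb - hab**2
    bad = ~((haa < 0) & (detH > 0))
    haa = np.where(bad, -1.0, haa)
    hbb = np.where(bad, -1.0, hbb)
    hab = np.where(bad, 0.0, hab)
    mode[bad] = 0.0
    detH = haa * hbb - hab**2
    # S = chol(inv(-H)); for 2x2, closed form
    # inv(-H) = 1/detH * [[-hbb, hab], [hab, -haa]] ... careful with signs:
    # -H = [[-haa, -hab], [-hab, -hbb]]; inv(-H) = (1/detH)*[[-hbb, hab],[hab, -haa]]
    s11 = -hbb / detH
    s12 = hab / detH
    s22 = -haa / detH
    c11 = np.sqrt(s11)
    c21 = s12 / c11
    c22 = np.sqrt(np.maximum(s22 - c21**2, 1e-300))
    a = mode[:, 0:1] + c11[:, None] * z1
    b = mode[:, 1:2] + c21[:, None] * z1 + c22[:, None] * z2
    vals = h(a, b) + 0.5 * (z1**2 + z2**2)
    logdetS = np.log(c11) + np.log(c22)
    return logdetS + logsumexp(logw[None, :] + vals, axis=1)


def log_marginal_subjects_1d(cond_loglik, n_subjects, rule=20, adaptive=True):
    """Per-subject log marginal over a single standard-normal random effect.

    ``cond_loglik(a)``: (n_subjects, m) -> (n_subjects, m); the caller maps
    the standardised effect a ~ N(0,1) to its natural scale internally.
    """
    rule = _as_rule(rule)
    n = int(n_subjects)
    z = rule.nodes[None, :]
    with np.errstate(divide="ignore"):
        logw = np.log(rule.weights)[None, :]
    if not adaptive:
        vals = cond_loglik(np.broadcast_to(z, (n, z.shape[1])))
        return logsumexp(logw + vals, axis=1)

    def h(a):
        return cond_loglik(a) - 0.5 * a**2

    mode, hess = _fd_mode_newton(h, 1, n)
    hess = np.where(hess < -1e-8, hess, -1.0)
    s = 1.0 / np.sqrt(-hess)
    a = mode + s[:, None] * z
    vals = h(a) + 0.5 * z**2
    return np.log(s) + logsumexp(logw + vals, axis=1)


def adaptive_center(logf, cov, rule=20) -> float:
    """Adaptively centred log integral of exp(logf) against N(0, cov).

    Scalar convenience wrapper around the vectorised engines: accepts a
    1-element covariance (or scalar variance) for a single effect, or a 2x2
    covariance for a pair.  Falls back to the non-adaptive rule if the mode
    search does not find usable curvature (the engine's internal guard).
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if cov.shape == (1, 1):
        sd = float(np.sqrt(cov[0, 0]))

        def cl(a):
            return np.vectorize(lambda t: logf(sd * t))(a)

        return float(log_marginal_subjects_1d(cl, 1, rule=rule, adaptive=True)[0])
    if cov.shape != (2, 2):
        raise ValueError("cov must be scalar-like or 2x2")

    def cl2(u, v):
        return np.vectorize(logf)(u, v)

    return float(log_marginal_subjects_2d(cl2, 1, cov, rule=rule, adaptive=True)[0])
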