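"""Shared fitting machinery: optimisation, covariances, tests.

All model families in this package maximise a marginal log-likelihood by
quasi-Newton optimisation on an unconstrained scale (log for variances and
positive parameters, atanh for correlations, logit for probabilities and the
bridge parameter).  Standard errors come from a central-finite-difference
Hessian of the log-likelihood, mapped back to the natural scale by the delta
method; an optional sandwich covariance uses per-subject score outer products
(subjects are the independent units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ParamTransform",
    "FitResult",
    "numerical_hessian",
    "maximize",
    "sandwich_cov",
    "aic",
    "lrt",
]


_TRANSFORMS = {
    "identity": (lambda x: x, lambda y: y, lambda x: np.ones_like(np.asarray(x, float))),
    "log": (np.exp, np.log, np.exp),
    "atanh": (np.tanh, np.arctanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "logit": (
        lambda x: 1.0 / (1.0 + np.exp(-x)),
        lambda p: np.log(p) - np.log1p(-p),
        lambda x: np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))) ** 2,
    ),
}


@dataclass(frozen=True)
class ParamTransform:
    """Names + per-parameter link between unconstrained and natural scales."""

    names: tuple
    links: tuple  # each one of 'identity', 'log', 'atanh', 'logit'

    def __post_init__(self):
        if len(self.names) != len(self.links):
            raise ValueError("names and links must have equal length")
        for l in self.links:
            if l not in _TRANSFORMS:
                raise ValueError(f"unknown link {l!r}")

    @property
    def k(self) -> int:
        return len(self.names)

    def to_natural(self, x):
        x = np.asarray(x, dtype=float)
        return np.array([_TRANSFORMS[l][0](xi) for l, xi in zip(self.links, x)])

    def to_unconstrained(self, theta):
        theta = np.asarray(theta, dtype=float)
        return np.array([_TRANSFORMS[l][1](ti) for l, ti in zip(self.links, theta)])

    def jacobian_diag(self, x):
        x = np.asarray(x, dtype=float)
        return np.array([_TRANSFORMS[l][2](xi) for l, xi in zip(self.links, x)])


@dataclass
class FitResult:
    """Maximum-likelihood fit summary on the natural parameter scale."""

    names: tuple
    estimates: np.ndarray
    loglik: float
    cov_model: np.ndarray
    converged: bool
    n_subjects: int
    n_obs: int
    quad_order: int
    cov_robust: np.ndarray | None = None
    message: str = ""
    x_unconstrained: np.ndarray | None = None
    transform: ParamTransform | None = None
    cov_unconstrained: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def neg2loglik(self) -> float:
        return -2.0 * self.loglik

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.cov_model), 0.0))

    @property
    def se_robust(self) -> np.ndarray | None:
        if self.cov_robust is None:
            return None
        return np.sqrt(np.maximum(np.diag(self.cov_robust), 0.0))

    def __getitem__(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def wald_ci(self, level: float = 0.95, robust: bool = False):
        """Wald intervals computed on the unconstrained scale and mapped back
        (keeps variance and probability parameters inside their domains)."""
        z = stats.norm.ppf(0.5 * (1 + level))
        if robust and self.cov_robust is None:
            raise ValueError("no robust covariance available")
        if self.x_unconstrained is None or self.transform is None:
            cov = self.cov_robust if robust else self.cov_model
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            return np.column_stack([self.estimates - z * se, self.estimates + z * se])
        J = self.transform.jacobian_diag(self.x_unconstrained)
        cov = self.cov_robust if robust else self.cov_model
        with np.errstate(divide="ignore", invalid="ignore"):
            se_u = np.where(J > 0, np.sqrt(np.maximum(np.diag(cov), 0.0)) / J, 0.0)
        lo = self.transform.to_natural(self.x_unconstrained - z * se_u)
        hi = self.transform.to_natural(self.x_unconstrained + z * se_u)
        return np.column_stack([np.minimum(lo, hi), np.maximum(lo, hi)])

    def to_dict(self) -> dict:
        out = {
            "estimates": {n: float(v) for n, v in zip(self.names, self.estimates)},
            "se": {n: float(v) for n, v in zip(self.names, self.se)},
            "loglik": float(self.loglik),
            "neg2loglik": float(self.neg2loglik),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "n_subjects": int(self.n_subjects),
            "n_obs": int(self.n_obs),
            "quad_order": int(self.quad_order),
        }
        if self.cov_robust is not None:
            out["se_robust"] = {
                n: float(v) for n, v in zip(self.names, self.se_robust)
            }
        out.update({k: v for k, v in self.extra.items()})
        return out

    def summary(self) -> str:
        lines = [f"{'parameter':<22}{'estimate':>12}{'se':>12}"]
        for n, e, s in zip(self.names, self.estimates, self.se):
            lines.append(f"{n:<22}{e:>12.4f}{s:>12.4f}")
        lines.append(
            f"loglik {self.loglik:.4f}  AIC {self.aic:.4f}  "
            f"converged={self.converged}  N={self.n_subjects}  n_obs={self.n_obs}"
        )
        return "\n".join(lines)


def numerical_hessian(f, x, rel_step: float = None):
    """Central-finite-difference Hessian of scalar f at x.

    Step per coordinate is cbrt(eps) * max(1, |x_i|) unless overridden.
    """
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = (rel_step or np.finfo(float).eps ** (1.0 / 3.0)) * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


def _newton_polish(neg, x, steps=2):
    """A couple of damped Newton steps after BFGS.

    BFGS with finite-difference gradients stalls around 1e-6 of the optimum;
    central-difference Newton steps recover close-to-quadratic accuracy.
    Steps are only accepted if they improve the objective.
    """
    x = np.asarray(x, dtype=float)
    k = len(x)
    f0 = neg(x)
    for _ in range(steps):
        h = 1e-6 * np.maximum(1.0, np.abs(x))
        g = np.empty(k)
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            g[i] = (neg(x + e) - neg(x - e)) / (2 * h[i])
        if np.max(np.abs(g)) < 1e-9:
            break
        H = numerical_hessian(neg, x)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        norm = np.linalg.norm(step)
        if not np.isfinite(norm) or norm > 1.0:
            break
        f1 = neg(x - step)
        if not np.isfinite(f1) or f1 > f0 + 1e-12:
            break
        x = x - step
        f0 = f1
        if norm < 1e-10:
            break
    return x


def _safe_inverse(A):
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A)


def maximize(
    loglik_unconstrained,
    init_unconstrained,
    transform: ParamTransform,
    n_subjects: int,
    n_obs: int,
    quad_order: int = 20,
    per_subject_loglik=None,
    robust: bool = False,
    compute_cov: bool = True,
    maxiter: int = 500,
    gtol: float = 1e-5,
) -> FitResult:
    """Quasi-Newton maximisation of a log-likelihood on the unconstrained scale.

    ``loglik_unconstrained(x)`` returns the total log-likelihood; the
    optional ``per_subject_loglik(x)`` returns the length-N vector of subject
    contributions and enables the sandwich covariance.
    """
    x0 = np.asarray(init_unconstrained, dtype=float)

    def neg(x):
        v = loglik_unconstrained(x)
        if not np.isfinite(v):
            return 1e12
        return -v

    res = optimize.minimize(
        neg, x0, method="BFGS", options={"maxiter": maxiter, "gtol": gtol}
    )
    x = _newton_polish(neg, res.x)
    ll = -neg(x)
    # BFGS with finite-difference gradients often exits with a spurious
    # "precision loss" near the optimum; a small gradient norm is what counts
    grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 1e-3 * max(1.0, abs(ll) / 100.0)
    converged = bool(res.success or grad_ok)
    J = transform.jacobian_diag(x)
    cov_rob = None
    if compute_cov:
        H = numerical_hessian(lambda t: -loglik_unconstrained(t), x)
        cov_u = _safe_inverse(H)
        cov_u = 0.5 * (cov_u + cov_u.T)
        cov_nat = cov_u * np.outer(J, J)
        if robust:
            if per_subject_loglik is None:
                raise ValueError("per_subject_loglik required for robust covariance")
            cov_rob_u = sandwich_cov(per_subject_loglik, x, H)
            cov_rob = cov_rob_u * np.outer(J, J)
    else:
        cov_u = np.full((len(x), len(x)), np.nan)
        cov_nat = cov_u
    return FitResult(
        names=transform.names,
        estimates=transform.to_natural(x),
        loglik=float(ll),
        cov_model=cov_nat,
        cov_robust=cov_rob,
        converged=converged,
        n_subjects=n_subjects,
        n_obs=n_obs,
        quad_order=quad_order,
        message=str(res.message),
        x_unconstrained=x,
        transform=transform,
        cov_unconstrained=cov_u,
    )


def sandwich_cov(per_subject_loglik, x, hessian_negloglik=None):
    """Sandwich covariance A^{-1} B A^{-1} on the scale of ``x``.

    A is the observed information (Hessian of the negative log-likelihood)
    and B the sum of per-subject score outer products, the scores obtained by
    central finite differences of the per-subject log-likelihood vector.
    """
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = np.finfo(float).eps ** (1.0 / 3.0) * np.maximum(1.0, np.abs(x))
    scores = []
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        scores.append(
            (np.asarray(per_subject_loglik(x + e)) - np.asarray(per_subject_loglik(x - e)))
            / (2.0 * h[i])
        )
    S = np.column_stack(scores)  # (N, k)
    B = S.T @ S
    if hessian_negloglik is None:
        hessian_negloglik = numerical_hessian(
            lambda t: -float(np.sum(per_subject_loglik(t))), x
        )
    cond = np.linalg.cond(hessian_negloglik)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"information matrix is singular (condition number {cond:.3g})"
        )
    Ainv = np.linalg.inv(hessian_negloglik)
    V = Ainv @ B @ Ainv.T
    return 0.5 * (V + V.T)


def aic(fit: FitResult) -> float:
    """Akaike information criterion -2 loglik + 2 k."""
    return fit.aic


def lrt(fit_full: FitResult, fit_null: FitResult, df: int = None, boundary: bool = False):
    """Likelihood-ratio test of nested fits on identical data.

    With ``boundary=True`` the null value lies on the boundary of the
    parameter space and the reference distribution is the 50:50 mixture of a
    point mass at zero and chi-square(1).
    """
    if fit_full.n_obs != fit_null.n_obs or fit_full.n_subjects != fit_null.n_subjects:
        raise ValueError("fits are not on identical data")
    T = 2.0 * (fit_full.loglik - fit_null.loglik)
    if T < -1e-6:
        raise ValueError(
            f"negative LR statistic {T:.3g}: the nested fit exceeds the full fit; refit"
        )
    T = max(T, 0.0)
    if df is None:
        df = fit_full.k - fit_null.k
    if boundary:
        from .moverstayer import boundary_lrt_pvalue

        p = boundary_lrt_pvalue(T)
    else:
        p = float(stats.chi2.sf(T, df)) if T > 0 else 1.0
    return T, p
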