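"""Random-effect distributions for two-part longitudinal models.

Four families live here:

* the **bridge** distribution of Wang & Louis -- the random-intercept law for
  a logistic model under which the marginal (integrated) model is again
  logistic, with coefficients attenuated by a factor ``phi`` in (0, 1);
* **unit-mean gamma** and **unit-mean inverse-Gaussian** frailties for the
  mover part of mover-stayer count models (unit means fix the scale so the
  baseline intensity stays identifiable);
* the **compound Poisson** frailty U = sum_{j<=K} L_j with K ~ Poisson(rate)
  and L_j ~ Exp(summand_rate), whose point mass exp(-rate) at zero makes it a
  mover-stayer law with the stayer probability tied to the rate.

Every density is exposed in log form; likelihood code consumes only the log
versions (underflow control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ive, ndtr

__all__ = [
    "BridgeParams",
    "BivariateNormalRE",
    "MoverStayerRE",
    "bridge_pdf",
    "bridge_logpdf",
    "bridge_variance",
    "phi_from_variance",
    "bridge_inverse_cdf",
    "sample_bridge_normal_pair",
    "unit_gamma_pdf",
    "unit_gamma_logpdf",
    "unit_invgauss_pdf",
    "unit_invgauss_logpdf",
    "cp_pdf",
    "cp_logpdf",
    "cp_stayer_prob",
    "sample_frailty",
]


# --------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class BridgeParams:
    """Bridge distribution parameter phi in (0, 1).

    Implied variance is pi^2 (phi^-2 - 1) / 3, strictly decreasing in phi;
    phi -> 1 collapses the random intercept to zero.
    """

    phi: float

    def __post_init__(self):
        if not (0.0 < self.phi < 1.0):
            raise ValueError(f"phi must lie in (0, 1), got {self.phi}")

    @property
    def variance(self) -> float:
        return bridge_variance(self.phi)


@dataclass(frozen=True)
class BivariateNormalRE:
    """Jointly normal random-intercept pair with correlation rho."""

    var_u: float
    var_v: float
    rho: float = 0.0

    def __post_init__(self):
        if self.var_u < 0 or self.var_v < 0:
            raise ValueError("variances must be nonnegative")
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")

    @property
    def cov(self) -> np.ndarray:
        c = self.rho * np.sqrt(self.var_u * self.var_v)
        return np.array([[self.var_u, c], [c, self.var_v]])


_MS_FAMILIES = ("gamma", "inverse_gaussian", "compound_poisson")


@dataclass(frozen=True)
class MoverStayerRE:
    """Two-part frailty law: point mass (stayers) plus a positive density.

    For the gamma and inverse-Gaussian families the continuous part has unit
    mean and ``stayer_prob`` is free.  For the compound-Poisson family the
    stayer probability is not free: it equals exp(-cp_rate), the atom of the
    compound-Poisson law at zero, and the full-distribution mean is
    cp_rate / cp_summand_rate.
    """

    family: str
    stayer_prob: float = 0.0
    gamma_dispersion: float | None = None
    ig_shape: float | None = None
    cp_rate: float | None = None
    cp_summand_rate: float | None = None

    def __post_init__(self):
        if self.family not in _MS_FAMILIES:
            raise ValueError(f"family must be one of {_MS_FAMILIES}")
        if self.family == "gamma":
            if self.gamma_dispersion is None or self.gamma_dispersion <= 0:
                raise ValueError("gamma_dispersion must be positive")
        elif self.family == "inverse_gaussian":
            if self.ig_shape is None or self.ig_shape <= 0:
                raise ValueError("ig_shape must be positive")
        else:
            if self.cp_rate is None or self.cp_rate <= 0:
                raise ValueError("cp_rate must be positive")
            if self.cp_summand_rate is None or self.cp_summand_rate <= 0:
                raise ValueError("cp_summand_rate must be positive")
            pi = float(np.exp(-self.cp_rate))
            object.__setattr__(self, "stayer_prob", pi)
        if not (0.0 <= self.stayer_prob <= 1.0):
            raise ValueError("stayer_prob must lie in [0, 1]")

    def continuous_logpdf(self, u):
        """Log density of the continuous (mover) part, unnormalised to mass
        1 - stayer_prob for the CP family and to 1 for gamma/IG."""
        if self.family == "gamma":
            return unit_gamma_logpdf(u, self.gamma_dispersion)
        if self.family == "inverse_gaussian":
            return unit_invgauss_logpdf(u, self.ig_shape)
        return cp_logpdf(u, self.cp_rate, self.cp_summand_rate)


# --------------------------------------------------------------------------
# bridge distribution

def bridge_logpdf(b, phi: float):
    _check_phi(phi)
    b = np.asarray(b, dtype=float)
    # log[ sin(phi pi) / (2 pi (cosh(phi b) + cos(phi pi))) ], stable in |b|
    x = phi * b
    ax = np.abs(x)
    # cosh(x) + c = exp(ax) * (1 + exp(-2 ax)) / 2 + c
    log_den = ax + np.log1p(np.exp(-2.0 * ax) + 2.0 * np.cos(phi * np.pi) * np.exp(-ax)) - np.log(2.0)
    return np.log(np.sin(phi * np.pi)) - np.log(2.0 * np.pi) - log_den


def bridge_pdf(b, phi: float):
    """Density of the bridge distribution: sin(phi pi) / (2 pi (cosh(phi b) + cos(phi pi)))."""
    return np.exp(bridge_logpdf(b, phi))


def bridge_variance(phi: float) -> float:
    """Variance pi^2 (phi^-2 - 1)/3 of the bridge distribution."""
    _check_phi(phi)
    return np.pi**2 * (phi**-2 - 1.0) / 3.0


def phi_from_variance(var_b: float) -> float:
    """Inverse of ``bridge_variance``."""
    if var_b <= 0:
        raise ValueError("variance must be positive")
    return float(1.0 / np.sqrt(3.0 * var_b / np.pi**2 + 1.0))


def bridge_inverse_cdf(x, phi: float):
    """Bridge quantile function (1/phi) log[sin(phi pi x) / sin(phi pi (1-x))].

    Strictly increasing on (0, 1) and antisymmetric about x = 1/2.
    """
    _check_phi(phi)
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("x must lie strictly in (0, 1)")
    return (np.log(np.sin(phi * np.pi * x)) - np.log(np.sin(phi * np.pi * (1.0 - x)))) / phi


def sample_bridge_normal_pair(rho: float, var_v: float, phi: float, n: int, seed=None):
    """Correlated (B, V) pair: B bridge(phi) marginal, V ~ N(0, var_v).

    Constructed from a bivariate normal (U, V) with corr(U, V) = rho via the
    probability integral transform B = F_B^{-1}(Phi(U)); the (B, V)
    correlation is approximately rho (Wang-Louis construction).
    """
    _check_phi(phi)
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [-1, 1]")
    if var_v <= 0:
        raise ValueError("var_v must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((int(n), 2))
    u = z[:, 0]
    v = np.sqrt(var_v) * (rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1])
    # clip the uniform away from {0,1} to keep the quantile finite
    p = np.clip(ndtr(u), 1e-15, 1.0 - 1e-15)
    b = bridge_inverse_cdf(p, phi)
    return b, v


def _check_phi(phi):
    if not (0.0 < phi < 1.0):
        raise ValueError(f"phi must lie in (0, 1), got {phi}")


# --------------------------------------------------------------------------
# positive frailty densities

def unit_gamma_logpdf(u, dispersion: float):
    """Log density of Gamma(shape = rate = 1/dispersion): unit mean, variance
    ``dispersion``."""
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("u must be positive")
    r = 1.0 / dispersion
    return r * np.log(r) - gammaln(r) + (r - 1.0) * np.log(u) - r * u


def unit_gamma_pdf(u, dispersion: float):
    return np.exp(unit_gamma_logpdf(u, dispersion))


def unit_invgauss_logpdf(u, shape: float):
    """Log density of the inverse Gaussian with mean 1 and shape psi:
    sqrt(psi/(2 pi u^3)) exp(-psi (u-1)^2 / (2u))."""
    if shape <= 0:
        raise ValueError("shape must be positive")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("u must be positive")
    return 0.5 * (np.log(shape) - np.log(2.0 * np.pi) - 3.0 * np.log(u)) - shape * (u - 1.0) ** 2 / (2.0 * u)


def unit_invgauss_pdf(u, shape: float):
    return np.exp(unit_invgauss_logpdf(u, shape))


def cp_logpdf(u, cp_rate: float, cp_summand_rate: float):
    """Log density of the continuous part of the compound-Poisson frailty.

    g(u) = exp(-rate - nu u) sqrt(nu rate / u) I_1(2 sqrt(nu rate u)) on
    u > 0; the full law adds a point mass exp(-rate) at zero.  The Bessel
    factor is evaluated in exponentially scaled form so large arguments do
    not overflow.
    """
    if cp_rate <= 0 or cp_summand_rate <= 0:
        raise ValueError("cp_rate and cp_summand_rate must be positive")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("u must be positive (the atom at 0 is separate)")
    nu = cp_summand_rate
    h = 2.0 * np.sqrt(nu * cp_rate * u)
    # log I_1(h) = log ive(1, h) + h   (ive is e^{-h} I_1(h))
    log_bessel = np.log(ive(1, h)) + h
    return -cp_rate - nu * u + 0.5 * (np.log(nu * cp_rate) - np.log(u)) + log_bessel


def cp_pdf(u, cp_rate: float, cp_summand_rate: float):
    return np.exp(cp_logpdf(u, cp_rate, cp_summand_rate))


def cp_stayer_prob(cp_rate: float) -> float:
    """Point mass exp(-rate) of the compound-Poisson frailty at zero."""
    if cp_rate <= 0:
        raise ValueError("cp_rate must be positive")
    return float(np.exp(-cp_rate))


def sample_frailty(re: MoverStayerRE, n: int, seed=None) -> np.ndarray:
    """Draw n frailty values from a mover-stayer law (stayers give u = 0)."""
    rng = np.random.default_rng(seed)
    n = int(n)
    if re.family == "gamma":
        r = 1.0 / re.gamma_dispersion
        u = rng.gamma(shape=r, scale=1.0 / r, size=n)
    elif re.family == "inverse_gaussian":
        u = rng.wald(1.0, re.ig_shape, size=n)
    else:
        k = rng.poisson(re.cp_rate, size=n)
        u = np.array([rng.gamma(shape=ki, scale=1.0 / re.cp_summand_rate) if ki > 0 else 0.0
                      for ki in k])
        return u
    stay = rng.random(n) < re.stayer_prob
    u[stay] = 0.0
    return u
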