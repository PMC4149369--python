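"""Exponential-family response distributions and link functions.

Each family has density exp{[z*theta - b(theta)]/phi + c(z, phi)} with a
dispersion phi common to all observations and variance Var(Z) = phi * V(mu).
The three families used for transformed species richness are the normal
(V = 1), gamma (V = mu**2) and inverse Gaussian (V = mu**3); the latter two
require a strictly positive response and mean.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special

__all__ = ["Family", "Normal", "Gamma", "InverseGaussian",
           "Link", "IdentityLink", "ReciprocalLink", "InverseSquaredLink",
           "LogLink", "get_family", "get_link"]


# --------------------------------------------------------------------------
# Links

class Link:
    """Monotone differentiable map g from the mean to the linear predictor."""

    name: str

    def g(self, mu):
        raise NotImplementedError

    def inverse(self, eta):
        raise NotImplementedError

    def deriv(self, mu):
        """g'(mu)."""
        raise NotImplementedError


class IdentityLink(Link):
    name = "identity"

    def g(self, mu):
        return np.asarray(mu, float)

    def inverse(self, eta):
        return np.asarray(eta, float)

    def deriv(self, mu):
        return np.ones_like(np.asarray(mu, float))


class ReciprocalLink(Link):
    """g(mu) = 1/mu — the gamma canonical link up to sign, mu > 0."""

    name = "reciprocal"

    def g(self, mu):
        return 1.0 / np.asarray(mu, float)

    def inverse(self, eta):
        return 1.0 / np.asarray(eta, float)

    def deriv(self, mu):
        return -1.0 / np.asarray(mu, float) ** 2


class InverseSquaredLink(Link):
    """g(mu) = 1/mu**2 — the inverse-Gaussian canonical link, mu > 0."""

    name = "inverse_squared"

    def g(self, mu):
        return 1.0 / np.asarray(mu, float) ** 2

    def inverse(self, eta):
        return 1.0 / np.sqrt(np.asarray(eta, float))

    def deriv(self, mu):
        return -2.0 / np.asarray(mu, float) ** 3


class LogLink(Link):
    name = "log"

    def g(self, mu):
        return np.log(mu)

    def inverse(self, eta):
        return np.exp(np.asarray(eta, float))

    def deriv(self, mu):
        return 1.0 / np.asarray(mu, float)


# --------------------------------------------------------------------------
# Families

class Family:
    name: str
    canonical_link: str
    positive_support: bool

    def variance(self, mu):
        """Variance function V(mu)."""
        raise NotImplementedError

    def in_support(self, x) -> bool:
        x = np.asarray(x, float)
        if not np.all(np.isfinite(x)):
            return False
        return bool(np.all(x > 0)) if self.positive_support else True

    def loglik(self, z, mu, phi) -> float:
        """Sum of log densities at dispersion phi."""
        raise NotImplementedError

    def deviance(self, z, mu) -> float:
        """Scaled deviance (phi-free), used as the IRLS convergence gauge."""
        raise NotImplementedError

    def dispersion_mle(self, z, mu) -> float:
        """Profile-out phi: its MLE given the fitted means."""
        raise NotImplementedError

    def sample(self, rng, mu, phi):
        """Draw one value per mean at dispersion phi."""
        raise NotImplementedError


class Normal(Family):
    name = "normal"
    canonical_link = "identity"
    positive_support = False

    def variance(self, mu):
        return np.ones_like(np.asarray(mu, float))

    def loglik(self, z, mu, phi):
        z, mu = np.asarray(z, float), np.asarray(mu, float)
        n = z.size
        return float(-0.5 * n * np.log(2 * np.pi * phi)
                     - 0.5 * np.sum((z - mu) ** 2) / phi)

    def deviance(self, z, mu):
        return float(np.sum((np.asarray(z, float) - mu) ** 2))

    def dispersion_mle(self, z, mu):
        z = np.asarray(z, float)
        return float(np.sum((z - mu) ** 2) / z.size)

    def sample(self, rng, mu, phi):
        return rng.normal(mu, np.sqrt(phi))


class Gamma(Family):
    """Gamma with mean mu and shape 1/phi: Var(Z) = phi * mu**2."""

    name = "gamma"
    canonical_link = "reciprocal"
    positive_support = True

    def variance(self, mu):
        return np.asarray(mu, float) ** 2

    def loglik(self, z, mu, phi):
        z, mu = np.asarray(z, float), np.asarray(mu, float)
        nu = 1.0 / phi
        return float(np.sum(nu * np.log(nu * z / mu) - np.log(z)
                            - nu * z / mu - special.gammaln(nu)))

    def deviance(self, z, mu):
        z, mu = np.asarray(z, float), np.asarray(mu, float)
        return float(2.0 * np.sum(-np.log(z / mu) + (z - mu) / mu))

    def dispersion_mle(self, z, mu):
        # dl/dnu = n[ln nu + 1 - psi(nu)] + sum[ln(z/mu) - z/mu] = 0
        z, mu = np.asarray(z, float), np.asarray(mu, float)
        n = z.size
        const = float(np.sum(np.log(z / mu) - z / mu))

        def score(log_nu):
            nu = np.exp(log_nu)
            return n * (log_nu + 1.0 - special.digamma(nu)) + const

        lo, hi = np.log(1e-8), np.log(1e10)
        if score(lo) < 0:          # pathological: deviance ~ 0
            return 1e-8
        root = optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-12)
        return float(np.exp(-root))

    def sample(self, rng, mu, phi):
        nu = 1.0 / phi
        return rng.gamma(shape=nu, scale=np.asarray(mu, float) * phi)


class InverseGaussian(Family):
    """Inverse Gaussian with mean mu: Var(Z) = phi * mu**3."""

    name = "inverse_gaussian"
    canonical_link = "inverse_squared"
    positive_support = True

    def variance(self, mu):
        return np.asarray(mu, float) ** 3

    def loglik(self, z, mu, phi):
        z, mu = np.asarray(z, float), np.asarray(mu, float)
        return float(np.sum(-0.5 * np.log(2 * np.pi * phi * z ** 3)
                            - (z - mu) ** 2 / (2 * phi * mu ** 2 * z)))

    def deviance(self, z, mu):
        z, mu = np.asarray(z, float), np.asarray(mu, float)
        return float(np.sum((z - mu) ** 2 / (mu ** 2 * z)))

    def dispersion_mle(self, z, mu):
        z, mu = np.asarray(z, float), np.asarray(mu, float)
        return float(np.sum((z - mu) ** 2 / (mu ** 2 * z)) / z.size)

    def sample(self, rng, mu, phi):
        mu = np.asarray(mu, float)
        # scipy/wald parametrisation: shape lambda = 1/phi
        return rng.wald(mu, 1.0 / phi)


_FAMILIES = {"normal": Normal, "gamma": Gamma, "inverse_gaussian": InverseGaussian}
_LINKS = {"identity": IdentityLink, "reciprocal": ReciprocalLink,
          "inverse_squared": InverseSquaredLink, "log": LogLink}


def get_family(name: str) -> Family:
    try:
        return _FAMILIES[name]()
    except KeyError:
        raise ValueError(f"unknown family {name!r}; choose from "
                         f"{sorted(_FAMILIES)}") from None


def get_link(name: str) -> Link:
    try:
        return _LINKS[name]()
    except KeyError:
        raise ValueError(f"unknown link {name!r}; choose from "
                         f"{sorted(_LINKS)}") from None
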