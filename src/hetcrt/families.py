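"""Outcome families with canonical links.

Three exponential families are supported, each with its canonical link:
Gaussian/identity (continuous outcomes), Poisson/log (counts) and
Bernoulli/logit (binary outcomes).  All likelihood code in this package works
on (cluster, subgroup)-cell sufficient statistics rather than individual
observations: because the only covariates are the cluster-level arm indicator
and the person-level subgroup factor, the linear predictor is constant within
a cell, and each cell is summarized by its size ``m``, outcome sum ``S`` and
(for the Gaussian family) sum of squares ``SS``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln

__all__ = ["Family", "Gaussian", "Poisson", "Bernoulli", "get_family", "FAMILY_ALIASES"]


class Family:
    """Base class for an outcome family with its canonical link."""

    name: str = ""
    link: str = ""
    #: whether the family carries a free dispersion/residual-variance parameter
    has_scale: bool = False

    def mean(self, eta):
        """Inverse link: conditional mean as a function of the linear predictor."""
        raise NotImplementedError

    def weight(self, eta):
        """Canonical-link GLM weight d mu / d eta (= conditional variance)."""
        raise NotImplementedError

    def cell_loglik(self, eta, m, S, SS, scale=None):
        """Log-likelihood contribution of cells with linear predictor ``eta``.

        Exact (includes all normalizing constants except the Poisson
        ``-log y!`` term, which is data-only and added once per dataset by the
        caller so that absolute log-likelihood values are comparable across
        implementations).
        """
        raise NotImplementedError

    def cell_score(self, eta, m, S, scale=None):
        """d cell_loglik / d eta."""
        raise NotImplementedError

    def cell_weight(self, eta, m, scale=None):
        """-d^2 cell_loglik / d eta^2 (nonnegative for canonical links)."""
        raise NotImplementedError

    def simulate(self, rng, eta, scale=None):
        """Draw one outcome per linear-predictor entry."""
        raise NotImplementedError

    def loglik_constant(self, y):
        """Dataset-level additive constant (parameter-free)."""
        return 0.0

    def validate_outcome(self, y):
        pass

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"<Family {self.name}({self.link})>"


class Gaussian(Family):
    name = "gaussian"
    link = "identity"
    has_scale = True

    def mean(self, eta):
        return eta

    def weight(self, eta):
        return np.ones_like(eta)

    def cell_loglik(self, eta, m, S, SS, scale=None):
        return -0.5 * (m * np.log(2.0 * np.pi * scale)
                       + (SS - 2.0 * S * eta + m * eta ** 2) / scale)

    def cell_score(self, eta, m, S, scale=None):
        return (S - m * eta) / scale

    def cell_weight(self, eta, m, scale=None):
        return m / scale

    def simulate(self, rng, eta, scale=None):
        return eta + rng.normal(0.0, np.sqrt(scale), size=np.shape(eta))


class Poisson(Family):
    name = "poisson"
    link = "log"

    def mean(self, eta):
        return np.exp(np.clip(eta, -700, 30))

    def weight(self, eta):
        return self.mean(eta)

    def cell_loglik(self, eta, m, S, SS, scale=None):
        return S * eta - m * self.mean(eta)

    def cell_score(self, eta, m, S, scale=None):
        return S - m * self.mean(eta)

    def cell_weight(self, eta, m, scale=None):
        return m * self.mean(eta)

    def simulate(self, rng, eta, scale=None):
        return rng.poisson(self.mean(eta))

    def loglik_constant(self, y):
        return -float(np.sum(gammaln(np.asarray(y, dtype=float) + 1.0)))

    def validate_outcome(self, y):
        y = np.asarray(y)
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError("Poisson outcomes must be nonnegative integers")


class Bernoulli(Family):
    name = "bernoulli"
    link = "logit"

    def mean(self, eta):
        return expit(eta)

    def weight(self, eta):
        mu = expit(eta)
        return mu * (1.0 - mu)

    def cell_loglik(self, eta, m, S, SS, scale=None):
        return S * eta - m * np.logaddexp(0.0, eta)

    def cell_score(self, eta, m, S, scale=None):
        return S - m * expit(eta)

    def cell_weight(self, eta, m, scale=None):
        mu = expit(eta)
        return m * mu * (1.0 - mu)

    def simulate(self, rng, eta, scale=None):
        return (rng.random(size=np.shape(eta)) < expit(eta)).astype(np.int64)

    def validate_outcome(self, y):
        y = np.asarray(y)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("Bernoulli outcomes must be coded 0/1")


#: accepted spellings for each family (the trial-outcome vocabulary and the
#: distribution name are both common in practice)
FAMILY_ALIASES = {
    "gaussian": "gaussian", "normal": "gaussian", "continuous": "gaussian",
    "poisson": "poisson", "count": "poisson",
    "bernoulli": "bernoulli", "binary": "bernoulli", "binomial": "bernoulli",
}

_INSTANCES = {"gaussian": Gaussian(), "poisson": Poisson(), "bernoulli": Bernoulli()}


def get_family(family) -> Family:
    """Resolve a family name (or pass through a Family instance)."""
    if isinstance(family, Family):
        return family
    key = FAMILY_ALIASES.get(str(family).lower())
    if key is None:
        raise ValueError(f"unknown outcome family: {family!r}")
    return _INSTANCES[key]
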