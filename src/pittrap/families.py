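"""Marginal distribution families: CDF, point mass, quantile and log-likelihood.

Three marginal families are supported:

``"negative.binomial"``
    Counts with log link and quadratic mean-variance relationship
    ``Var(Y) = mu + psi * mu**2``.  ``psi`` is the overdispersion
    parameter (``psi = 1/size`` in the size/prob parameterization);
    ``psi = 0`` is the Poisson limit and is evaluated as such.
``"bernoulli"``
    0/1 responses with logit link; the ``psi`` argument is ignored.
``"gaussian"``
    Continuous responses with identity link; ``psi`` carries the
    standard deviation.  Included for the classical reductions of
    residual resampling (raw-residual bootstrap, permutation-style
    row resampling), not as a primary modelling family.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

#: dispersions below this are evaluated on the Poisson branch
PSI_POISSON = 1e-10

#: linear predictors are capped at +/- this value during fitting
ETA_CAP = 30.0

#: probabilities are clamped to (QUANTILE_EPS, 1 - QUANTILE_EPS) before inversion
QUANTILE_EPS = 1e-12

FAMILIES = ("negative.binomial", "bernoulli", "gaussian")

DISCRETE_FAMILIES = ("negative.binomial", "bernoulli")


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def _check_mean(mu, family: str) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if family == "negative.binomial":
        if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
            raise ValueError("negative binomial mean must be finite and > 0")
    elif family == "bernoulli":
        if np.any(~np.isfinite(mu)) or np.any(mu <= 0) or np.any(mu >= 1):
            raise ValueError("bernoulli mean must lie strictly in (0, 1)")
    return mu


def _nb_size_prob(mu, psi):
    """Map (mu, psi) to scipy's (size, prob) with Var = mu + psi mu^2."""
    size = 1.0 / psi
    prob = 1.0 / (1.0 + psi * np.asarray(mu, dtype=float))
    return size, prob


def nb_logpmf(y, mu, psi: float) -> np.ndarray:
    """Negative binomial log pmf, continued to non-integer ``y``.

    Non-integer support values arise when scoring Pearson-resampled
    pseudo-data; the gamma-function form of the pmf remains well defined
    and is used as the working log-likelihood there.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if psi < PSI_POISSON:
        return y * np.log(mu) - mu - special.gammaln(y + 1.0)
    r = 1.0 / psi
    logp = special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1.0)
    logp += y * (np.log(psi * mu) - np.log1p(psi * mu)) - r * np.log1p(psi * mu)
    return logp


def bernoulli_loglik(y, mu) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return y * np.log(mu) + (1.0 - y) * np.log1p(-mu)


def family_loglik(y, mu, psi: float, family: str) -> float:
    """Total log-likelihood of one response column."""
    _check_family(family)
    if family == "negative.binomial":
        return float(np.sum(nb_logpmf(y, mu, psi)))
    if family == "bernoulli":
        return float(np.sum(bernoulli_loglik(y, mu)))
    return float(np.sum(stats.norm.logpdf(np.asarray(y, float), mu, psi)))


def family_pmf(y, mu, psi: float = 0.0, family: str = "negative.binomial"):
    """Point mass P(Y = y) (density for the gaussian family)."""
    _check_family(family)
    mu = _check_mean(mu, family)
    y = np.asarray(y, dtype=float)
    if family == "negative.binomial":
        if psi < 0:
            raise ValueError("dispersion psi must be >= 0")
        if psi < PSI_POISSON:
            return stats.poisson.pmf(y, mu)
        size, prob = _nb_size_prob(mu, psi)
        return stats.nbinom.pmf(y, size, prob)
    if family == "bernoulli":
        return np.where(y >= 0.5, mu, 1.0 - mu)
    return stats.norm.pdf(y, mu, psi)


def family_cdf(y, mu, psi: float = 0.0, family: str = "negative.binomial"):
    """Marginal CDF F(y) at a support value.

    For discrete families the CDF is the usual right-continuous step
    function; the left limit F(y-) = F(y - 1) is exposed separately by
    :func:`family_cdf_lower`.
    """
    _check_family(family)
    mu = _check_mean(mu, family)
    y = np.asarray(y, dtype=float)
    if family == "negative.binomial":
        if psi < 0:
            raise ValueError("dispersion psi must be >= 0")
        if psi < PSI_POISSON:
            return stats.poisson.cdf(y, mu)
        size, prob = _nb_size_prob(mu, psi)
        return stats.nbinom.cdf(y, size, prob)
    if family == "bernoulli":
        return np.where(y >= 1.0, 1.0, np.where(y >= 0.0, 1.0 - mu, 0.0))
    return stats.norm.cdf(y, mu, psi)


def family_cdf_lower(y, mu, psi: float = 0.0, family: str = "negative.binomial"):
    """Left limit F(y-); equals F(y - 1) on integer support, F(y) if continuous."""
    _check_family(family)
    if family in DISCRETE_FAMILIES:
        return family_cdf(np.asarray(y, dtype=float) - 1.0, mu, psi, family)
    return family_cdf(y, mu, psi, family)


def family_quantile(u, mu, psi: float = 0.0, family: str = "negative.binomial"):
    """Generalized inverse CDF.

    For discrete families this returns the smallest support value ``y``
    with ``F(y) >= u`` so that ``F(y-) < u <= F(y)``.  ``u`` outside
    (0, 1) is clamped: non-positive values map to the minimum support
    value, values >= 1 are pulled back to ``1 - 1e-12`` before
    inversion.
    """
    _check_family(family)
    mu = _check_mean(mu, family)
    u = np.asarray(u, dtype=float)
    u = np.clip(u, QUANTILE_EPS, 1.0 - QUANTILE_EPS)
    if family == "negative.binomial":
        if psi < 0:
            raise ValueError("dispersion psi must be >= 0")
        if psi < PSI_POISSON:
            return stats.poisson.ppf(u, mu)
        size, prob = _nb_size_prob(mu, psi)
        return stats.nbinom.ppf(u, size, prob)
    if family == "bernoulli":
        return np.where(u <= 1.0 - mu, 0.0, 1.0)
    return stats.norm.ppf(u, mu, psi)


def family_variance(mu, psi: float, family: str):
    """Variance function evaluated at the mean."""
    _check_family(family)
    mu = np.asarray(mu, dtype=float)
    if family == "negative.binomial":
        return mu + psi * mu**2
    if family == "bernoulli":
        return mu * (1.0 - mu)
    return np.full_like(mu, psi**2)


def family_mean_derivative(mu, family: str):
    """d mu / d eta of the canonical-for-this-package link at the mean."""
    _check_family(family)
    mu = np.asarray(mu, dtype=float)
    if family == "negative.binomial":
        return mu
    if family == "bernoulli":
        return mu * (1.0 - mu)
    return np.ones_like(mu)
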