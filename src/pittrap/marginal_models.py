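"""Per-variable marginal regression fits.

Each response variable gets its own maximum-likelihood GLM fit:

* negative binomial with log link and quadratic variance
  ``Var(Y) = mu + psi mu^2`` — estimated by iteratively reweighted least
  squares on the regression coefficients nested inside a 1-D profile
  maximization over ``log psi``; the Poisson limit ``psi = 0`` is
  returned when the profile is maximized at the boundary;
* Bernoulli with logit link — plain IRLS with a linear-predictor cap to
  survive (quasi-)separation;
* gaussian with identity link — closed-form least squares, kept for the
  classical continuous-data reductions.

Sparse multivariate count tables routinely contain cells in which a
variable was never observed; under a saturated (interaction) model the
MLE of such a cell mean is 0 and the linear predictor diverges.  Fits
cap the linear predictor at ``+/- ETA_CAP`` and flag the column instead
of failing, so that resampling can proceed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .design import DesignSpec
from .families import (
    ETA_CAP,
    bernoulli_loglik,
    family_loglik,
    nb_logpmf,
)

__all__ = [
    "MarginalFit",
    "MarginalFitSet",
    "fit_negbin",
    "fit_bernoulli",
    "fit_gaussian",
    "fit_marginals",
]

#: IRLS iteration cap and relative log-likelihood tolerance
MAX_ITER = 200
LL_RTOL = 1e-8


@dataclass
class MarginalFit:
    """Fitted marginal regression for one response variable."""

    family: str
    coef: np.ndarray
    psi: float
    mu: np.ndarray
    eta: np.ndarray
    loglik: float
    converged: bool = True
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.flags = frozenset(self.flags)


@dataclass
class MarginalFitSet:
    """Column-wise marginal fits sharing one design."""

    fits: list[MarginalFit]
    design: DesignSpec
    family: str
    var_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.var_names:
            self.var_names = [f"y{j}" for j in range(len(self.fits))]

    def __len__(self) -> int:
        return len(self.fits)

    def __getitem__(self, j: int) -> MarginalFit:
        return self.fits[j]

    @property
    def mu(self) -> np.ndarray:
        """n x p matrix of fitted means."""
        return np.column_stack([f.mu for f in self.fits])

    @property
    def psi(self) -> np.ndarray:
        return np.array([f.psi for f in self.fits])

    @property
    def loglik(self) -> float:
        return float(sum(f.loglik for f in self.fits))

    @property
    def all_converged(self) -> bool:
        return all(f.converged for f in self.fits)


def _validate_counts(y: np.ndarray, allow_noninteger: bool) -> None:
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if np.any(y < 0):
        raise ValueError("count response contains negative values")
    if not allow_noninteger and np.any(y != np.round(y)):
        raise ValueError("count response contains non-integer values")


def _as_matrix(design) -> np.ndarray:
    return design.matrix if isinstance(design, DesignSpec) else np.asarray(design, float)


# ---------------------------------------------------------------------------
# negative binomial
# ---------------------------------------------------------------------------


def _irls_count(y, X, psi, beta0, max_iter=MAX_ITER, rtol=LL_RTOL):
    """IRLS for a log-link count model at fixed dispersion psi.

    Returns (beta, mu, eta, loglik, converged, capped).
    """
    beta = beta0.copy()
    eta = np.clip(X @ beta, -ETA_CAP, ETA_CAP)
    mu = np.exp(eta)
    ll = float(np.sum(nb_logpmf(y, mu, psi)))
    capped = False
    converged = False
    for _ in range(max_iter):
        # weights (dmu/deta)^2 / V = mu / (1 + psi mu); working response on eta scale
        w = mu / (1.0 + psi * mu)
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(X * np.sqrt(w)[:, None], np.sqrt(w) * z, rcond=None)[0]
        eta_new = X @ beta_new
        if np.any(np.abs(eta_new) > ETA_CAP):
            capped = True
            eta_new = np.clip(eta_new, -ETA_CAP, ETA_CAP)
        mu_new = np.exp(eta_new)
        ll_new = float(np.sum(nb_logpmf(y, mu_new, psi)))
        # step-halve if the likelihood drops (rare; guards capped updates)
        step = 1.0
        while ll_new < ll - 1e-10 and step > 1e-4:
            step *= 0.5
            beta_new = beta + step * (beta_new - beta)
            eta_new = np.clip(X @ beta_new, -ETA_CAP, ETA_CAP)
            mu_new = np.exp(eta_new)
            ll_new = float(np.sum(nb_logpmf(y, mu_new, psi)))
        done = abs(ll_new - ll) <= rtol * (abs(ll) + 1.0)
        beta, eta, mu, ll = beta_new, eta_new, mu_new, ll_new
        if done:
            converged = True
            break
    return beta, mu, eta, ll, converged, capped


def fit_negbin(
    y,
    design,
    warm: MarginalFit | None = None,
    allow_noninteger: bool = False,
    psi_max: float = 1e4,
) -> MarginalFit:
    """ML fit of a log-link negative binomial regression for one column.

    The profile log-likelihood over ``log psi`` is maximized with
    Brent's method; if the profile peaks at the lower boundary the
    Poisson limit (``psi = 0``) is returned with a ``"poisson_limit"``
    flag.  Saturated or empty cells cap the linear predictor and flag
    ``"capped"`` rather than raising.
    """
    X = _as_matrix(design)
    y = np.asarray(y, dtype=float)
    _validate_counts(y, allow_noninteger)
    if y.shape[0] != X.shape[0]:
        raise ValueError("response length does not match design rows")

    k = X.shape[1]
    if warm is not None and warm.coef.shape[0] == k:
        beta0 = warm.coef.copy()
    else:
        beta0 = np.zeros(k)
        beta0[0] = np.log(max(y.mean(), 1e-3))

    # Poisson fit: starting point and the psi -> 0 reference
    beta_p, mu_p, eta_p, ll_p, conv_p, cap_p = _irls_count(y, X, 0.0, beta0)

    state = {"beta": beta_p.copy()}

    def negprof(logpsi: float) -> float:
        psi = np.exp(logpsi)
        beta, mu, eta, ll, conv, cap = _irls_count(y, X, psi, state["beta"], max_iter=50)
        state["beta"] = beta
        return -ll

    lo, hi = np.log(1e-8), np.log(psi_max)
    res = minimize_scalar(
        negprof, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3}
    )
    psi_hat = float(np.exp(res.x))
    beta, mu, eta, ll, conv, cap = _irls_count(y, X, psi_hat, state["beta"])

    flags: set[str] = set()
    if ll <= ll_p + 1e-7 or psi_hat <= 2e-8:
        # profile maximized at the boundary: Poisson limit
        flags.add("poisson_limit")
        beta, mu, eta, ll, conv, cap = beta_p, mu_p, eta_p, ll_p, conv_p, cap_p
        psi_hat = 0.0
    if cap:
        flags.add("capped")
    if not conv:
        flags.add("not_converged")
    return MarginalFit("negative.binomial", beta, psi_hat, mu, eta, ll, conv, frozenset(flags))


# ---------------------------------------------------------------------------
# bernoulli
# ---------------------------------------------------------------------------


def fit_bernoulli(
    y,
    design,
    warm: MarginalFit | None = None,
    allow_noninteger: bool = False,
) -> MarginalFit:
    """ML logistic regression for one 0/1 column.

    Degenerate all-0/all-1 columns and separated configurations are
    returned with the linear predictor capped at ``+/- ETA_CAP`` and a
    flag instead of an exception, so resampling loops can proceed.
    ``allow_noninteger`` admits fractional responses in [0, 1] as
    produced by the truncated Pearson-residual bootstrap.
    """
    X = _as_matrix(design)
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y < 0) or np.any(y > 1):
        raise ValueError("bernoulli response must lie in [0, 1]")
    if not allow_noninteger and np.any((y != 0) & (y != 1)):
        raise ValueError("bernoulli response must be 0/1")
    if y.shape[0] != X.shape[0]:
        raise ValueError("response length does not match design rows")

    k = X.shape[1]
    beta = warm.coef.copy() if warm is not None and warm.coef.shape[0] == k else np.zeros(k)
    eta = np.clip(X @ beta, -ETA_CAP, ETA_CAP)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(bernoulli_loglik(y, mu)))
    converged = False
    capped = False
    for _ in range(MAX_ITER):
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(X * np.sqrt(w)[:, None], np.sqrt(w) * z, rcond=None)[0]
        eta = X @ beta
        if np.any(np.abs(eta) > ETA_CAP):
            capped = True
            eta = np.clip(eta, -ETA_CAP, ETA_CAP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-13, 1.0 - 1e-13)
        ll_new = float(np.sum(bernoulli_loglik(y, mu)))
        if abs(ll_new - ll) <= LL_RTOL * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    flags: set[str] = set()
    if capped:
        flags.add("capped")
    # |eta| beyond ~15 puts fitted probabilities within 3e-7 of 0/1:
    # practical (quasi-)separation for data-driven logits
    if np.any(np.abs(eta) > 15.0):
        flags.add("separation")
    if np.all(y == 0) or np.all(y == 1):
        flags.add("boundary")
    if not converged:
        flags.add("not_converged")
    return MarginalFit("bernoulli", beta, 0.0, mu, eta, ll, converged, frozenset(flags))


# ---------------------------------------------------------------------------
# gaussian
# ---------------------------------------------------------------------------


def fit_gaussian(y, design, warm=None, allow_noninteger: bool = True) -> MarginalFit:
    """Least-squares fit with the ML (1/n) scale estimate in ``psi``."""
    X = _as_matrix(design)
    y = np.asarray(y, dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu = X @ beta
    sigma = float(np.sqrt(np.mean((y - mu) ** 2)))
    flags: set[str] = set()
    if sigma <= 0:
        sigma = 1e-12
        flags.add("degenerate_scale")
    ll = family_loglik(y, mu, sigma, "gaussian")
    return MarginalFit("gaussian", beta, sigma, mu, mu, ll, True, frozenset(flags))


_FITTERS = {
    "negative.binomial": fit_negbin,
    "bernoulli": fit_bernoulli,
    "gaussian": fit_gaussian,
}


def fit_marginals(
    Y,
    design: DesignSpec,
    family: str = "negative.binomial",
    warm: MarginalFitSet | None = None,
    allow_noninteger: bool = False,
    var_names: list[str] | None = None,
) -> MarginalFitSet:
    """Fit every column of an n x p response matrix marginally."""
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] < 2:
        raise ValueError("need at least two observations")
    fitter = _FITTERS[family]
    fits = []
    for j in range(Y.shape[1]):
        w = warm.fits[j] if warm is not None else None
        fits.append(fitter(Y[:, j], design, warm=w, allow_noninteger=allow_noninteger))
    return MarginalFitSet(fits, design, family, var_names or [])
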