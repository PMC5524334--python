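"""Probability-integral-transform residuals and their inverse map.

For a fitted marginal CDF F the PIT-residual of an observation y is

    u = q F(y) + (1 - q) F(y-),     q ~ U(0, 1)      (discrete)
    u = F(y)                                          (continuous)

where F(y-) is the left limit of the CDF at y.  The jitter q spreads
the point mass of a discrete observation uniformly over the step of its
CDF, so that under a correctly specified model with known parameters
the u are exactly iid standard uniform.  Mapping z = Phi^{-1}(u) puts
residuals on the familiar normal scale for diagnostics and for
correlation estimation.

The inverse map (bootstrap step) sends a uniform value u* back to the
support: y* is the smallest support value with F(y*-) < u* <= F(y*).
Because each observed u lies inside the step of its own y, inverting
unresampled residuals reproduces the data exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .families import DISCRETE_FAMILIES, family_cdf, family_cdf_lower, family_quantile
from .marginal_models import MarginalFitSet

__all__ = [
    "PITResiduals",
    "compute_pit",
    "to_normal_scale",
    "rescale_residuals",
    "invert_pit",
    "pearson_residuals",
]

#: clamp width keeping u strictly inside (0, 1)
U_EPS = 1e-12


@dataclass
class PITResiduals:
    """Matrix of PIT-residuals with the jitter that produced them."""

    u: np.ndarray
    q: np.ndarray | None = None
    rescaled: bool = False
    scale_factors: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


def compute_pit(
    Y,
    fits: MarginalFitSet,
    q: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> PITResiduals:
    """Jittered PIT-residuals of an n x p response matrix.

    ``q`` may be supplied explicitly (same shape as ``Y``, entries in
    (0, 1)); otherwise it is drawn from ``rng``.  For continuous
    families the jitter is ignored.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    if len(fits) != p:
        raise ValueError(f"{len(fits)} fitted variables for {p} response columns")
    discrete = fits.family in DISCRETE_FAMILIES
    if q is None:
        if discrete:
            if rng is None:
                rng = np.random.default_rng()
            q = rng.uniform(size=(n, p))
        else:
            q = np.full((n, p), 0.5)
    else:
        q = np.asarray(q, dtype=float)
        if q.shape != Y.shape:
            raise ValueError("jitter matrix q must match the response shape")
        if np.any(q <= 0) or np.any(q >= 1):
            raise ValueError("jitter entries must lie strictly in (0, 1)")

    u = np.empty((n, p))
    for j in range(p):
        f = fits[j]
        upper = family_cdf(Y[:, j], f.mu, f.psi, f.family)
        if discrete:
            lower = family_cdf_lower(Y[:, j], f.mu, f.psi, f.family)
            u[:, j] = q[:, j] * upper + (1.0 - q[:, j]) * lower
        else:
            u[:, j] = upper
    np.clip(u, U_EPS, 1.0 - U_EPS, out=u)
    return PITResiduals(u=u, q=q if discrete else None)


def to_normal_scale(pit: PITResiduals | np.ndarray) -> np.ndarray:
    """Map residuals to z = Phi^{-1}(u); finite because u is clamped."""
    u = pit.u if isinstance(pit, PITResiduals) else np.asarray(pit, dtype=float)
    return stats.norm.ppf(np.clip(u, U_EPS, 1.0 - U_EPS))


def rescale_residuals(pit: PITResiduals, center: bool = False) -> PITResiduals:
    """Shrinkage correction for overfitting: rescale normal-scale residuals.

    Each column of z = Phi^{-1}(u) is divided by its sample standard
    deviation (denominator n - 1), then mapped back through Phi.  The
    model overfits in small samples, so |z| is biased downward; the
    division restores unit scale.  With ``center=True`` the column mean
    is removed before dividing (off by default: the rescaling formula
    divides only).  A zero-variance column keeps factor 1 untouched.
    """
    z = to_normal_scale(pit)
    mean = z.mean(axis=0) if center else np.zeros(z.shape[1])
    sd = z.std(axis=0, ddof=1)
    factors = np.where(sd > 0, sd, 1.0)
    z2 = (z - mean) / factors
    u2 = np.clip(stats.norm.cdf(z2), U_EPS, 1.0 - U_EPS)
    return PITResiduals(u=u2, q=pit.q, rescaled=True, scale_factors=factors)


def invert_pit(u_star, fits: MarginalFitSet) -> np.ndarray:
    """Map residuals back to the response scale via fitted quantiles.

    Cell (i, j) uses the fitted parameters of position i of variable j,
    so a residual row resampled onto position i inherits that row's
    design.
    """
    u_star = u_star.u if isinstance(u_star, PITResiduals) else np.asarray(u_star, float)
    if u_star.ndim == 1:
        u_star = u_star[:, None]
    n, p = u_star.shape
    if len(fits) != p:
        raise ValueError("residual matrix does not match fitted variables")
    Y = np.empty((n, p))
    for j in range(p):
        f = fits[j]
        mu = f.mu
        if mu.shape[0] != n:
            raise ValueError("fitted means do not match residual rows")
        Y[:, j] = family_quantile(u_star[:, j], mu, f.psi, f.family)
    return Y


def pearson_residuals(Y, fits: MarginalFitSet) -> np.ndarray:
    """(y - mu) / sqrt(V(mu)); the non-pivotal comparator residual."""
    from .families import family_variance

    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    r = np.empty_like(Y)
    for j in range(Y.shape[1]):
        f = fits[j]
        r[:, j] = (Y[:, j] - f.mu) / np.sqrt(family_variance(f.mu, f.psi, f.family))
    return r


def plot_residuals(Y, fits: MarginalFitSet, path=None):
    """Residual-vs-fitted panels on the Pearson and PIT (normal) scales.

    Returns the matplotlib figure; saves to ``path`` when given.
    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Y = np.asarray(Y, dtype=float)
    pr = pearson_residuals(Y, fits)
    z = to_normal_scale(compute_pit(Y, fits, rng=np.random.default_rng(0)))
    logmu = np.log(np.maximum(fits.mu, 1e-12))
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, res, title in ((axes[0], pr, "Pearson residuals"), (axes[1], z, "PIT residuals (normal scale)")):
        for j in range(Y.shape[1]):
            ax.scatter(logmu[:, j], res[:, j], s=12)
        ax.axhline(0.0, color="red", lw=0.8)
        ax.set_xlabel("log fitted mean")
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
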