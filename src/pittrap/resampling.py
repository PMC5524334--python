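"""Bootstrap resampling schemes for regression response matrices.

Four schemes are provided, all but the last keeping the design fixed:

``pit.trap``
    Resample whole rows (clusters) of PIT-residuals with replacement,
    then invert the fitted marginal CDFs at the destination row's
    parameters.  Row resampling preserves cross-variable dependence
    without modelling it; inversion keeps resampled values on the
    family support.  By default the jitter is redrawn for every
    resample and residuals are rescaled.
``parametric``
    Simulate the uniforms instead of resampling them: draw Gaussian
    copula vectors with a supplied correlation matrix (identity for the
    independence variant), transform to uniforms, invert.  Requires the
    joint correlation structure to be specified.
``pearson``
    Resample rows of Pearson residuals and reconstruct
    ``y* = mu + sqrt(V) r*``.  For discrete data this leaves the
    support: counts are truncated below at 0 (non-integer values kept),
    Bernoulli values truncated to [0, 1].  The scheme is included as
    the classical comparator, pathologies and all.
``case``
    Resample (design row, response row) pairs jointly; the resampled
    design can be rank-deficient (empty treatment x block cells), which
    is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import DesignSpec
from .families import family_variance
from .marginal_models import MarginalFitSet
from .pit_residuals import (
    PITResiduals,
    compute_pit,
    invert_pit,
    pearson_residuals,
    rescale_residuals,
)

__all__ = [
    "ResampleScheme",
    "ResampleDraw",
    "pit_trap_draw",
    "parametric_draw",
    "pearson_draw",
    "case_draw",
    "nearest_positive_definite",
]

SCHEME_NAMES = ("pit.trap", "parametric", "pearson", "case")
CORR_MODELS = ("shrunk", "exchangeable", "independence")


@dataclass
class ResampleScheme:
    """A named resampling strategy with its options."""

    name: str = "pit.trap"
    B: int = 999
    rejitter: bool = True
    rescale: bool = True
    corr_model: str = "shrunk"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme {self.name!r}; expected one of {SCHEME_NAMES}")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.corr_model not in CORR_MODELS:
            raise ValueError(f"unknown correlation model {self.corr_model!r}")


@dataclass
class ResampleDraw:
    """One bootstrap response matrix and how it was produced."""

    y_star: np.ndarray
    indices: np.ndarray | None = None
    u_star: np.ndarray | None = None
    design: DesignSpec | None = None
    flags: dict = field(default_factory=dict)


def nearest_positive_definite(R: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped repair of a symmetric matrix, rescaled to unit diagonal."""
    R = 0.5 * (R + R.T)
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= min_eig:
        return R
    vals = np.maximum(vals, min_eig)
    R2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def pit_trap_draw(
    Y,
    fits: MarginalFitSet,
    rng: np.random.Generator,
    pit: PITResiduals | None = None,
    rejitter: bool = True,
    rescale: bool = True,
    indices: np.ndarray | None = None,
) -> ResampleDraw:
    """One PIT-trap resample.

    With ``rejitter`` the jitter matrix and residuals are recomputed
    from ``Y`` and ``fits`` for this draw (the recommended default for
    discrete data); otherwise the precomputed ``pit`` is reused.  Rows
    of residuals are then resampled with replacement and inverted with
    the destination row's fitted parameters.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if rejitter or pit is None:
        pit = compute_pit(Y, fits, rng=rng)
        if rescale:
            pit = rescale_residuals(pit)
    if indices is None:
        indices = rng.integers(0, n, size=n)
    else:
        indices = np.asarray(indices)
    u_star = pit.u[indices]
    y_star = invert_pit(u_star, fits)
    return ResampleDraw(y_star=y_star, indices=indices, u_star=u_star)


def parametric_draw(
    fits: MarginalFitSet,
    R: np.ndarray,
    rng: np.random.Generator,
) -> ResampleDraw:
    """One parametric-bootstrap resample through a Gaussian copula.

    ``z_i ~ MVN(0, R)``, ``u*_ij = Phi(z_ij)``, then inversion of the
    fitted marginal CDFs.  ``R = I`` gives the independence variant.
    """
    p = len(fits)
    n = fits.mu.shape[0]
    R = np.asarray(R, dtype=float)
    if R.shape != (p, p):
        raise ValueError(f"correlation matrix must be {p} x {p}")
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("correlation matrix not positive definite; applying eigenvalue repair")
        L = np.linalg.cholesky(nearest_positive_definite(R))
    z = rng.standard_normal((n, p)) @ L.T
    u_star = stats.norm.cdf(z)
    y_star = invert_pit(u_star, fits)
    return ResampleDraw(y_star=y_star, u_star=u_star)


def pearson_draw(
    Y,
    fits: MarginalFitSet,
    rng: np.random.Generator,
    indices: np.ndarray | None = None,
) -> ResampleDraw:
    """One Pearson-residual bootstrap resample.

    Residual rows are resampled with replacement and rescaled onto the
    destination cells.  Out-of-support values are truncated (counted in
    ``flags``); non-integer count values are kept as-is and counted.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    r = pearson_residuals(Y, fits)
    if indices is None:
        indices = rng.integers(0, n, size=n)
    else:
        indices = np.asarray(indices)
    r_star = r[indices]
    mu = fits.mu
    sd = np.column_stack(
        [np.sqrt(family_variance(fits[j].mu, fits[j].psi, fits[j].family)) for j in range(p)]
    )
    y_star = mu + sd * r_star
    flags = {"n_truncated": 0, "n_noninteger": 0}
    if fits.family == "negative.binomial":
        flags["n_truncated"] = int(np.sum(y_star < 0))
        y_star = np.maximum(y_star, 0.0)
        flags["n_noninteger"] = int(np.sum(y_star != np.round(y_star)))
    elif fits.family == "bernoulli":
        flags["n_truncated"] = int(np.sum((y_star < 0) | (y_star > 1)))
        y_star = np.clip(y_star, 0.0, 1.0)
        flags["n_noninteger"] = int(np.sum((y_star != 0.0) & (y_star != 1.0)))
    return ResampleDraw(y_star=y_star, indices=indices, flags=flags)


def case_draw(
    Y,
    design: DesignSpec,
    rng: np.random.Generator,
    indices: np.ndarray | None = None,
    cell_factors: tuple[str, ...] | None = None,
) -> ResampleDraw:
    """Joint with-replacement resampling of design and response rows.

    The resampled design keeps the parent's level coding.  A validity
    flag records whether any combination of the categorical factors
    present in the original data is empty in the resample (the source
    of rank deficiency for interaction tests).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if indices is None:
        indices = rng.integers(0, n, size=n)
    else:
        indices = np.asarray(indices)
    sub = design.subset(indices)
    factors = cell_factors or tuple(design.levels.keys())
    flags = {}
    if factors:
        orig_cells = set(map(tuple, design.data[list(factors)].astype(str).to_numpy()))
        new_cells = set(map(tuple, sub.data[list(factors)].astype(str).to_numpy()))
        flags["empty_cell"] = bool(orig_cells - new_cells)
    flags["rank_deficient"] = not sub.full_rank()
    return ResampleDraw(y_star=Y[indices], indices=indices, design=sub, flags=flags)
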