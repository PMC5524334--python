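"""Synthetic data generators and type-I-error experiments.

Three regimes mirror the study conditions of the method's evaluation:

``logistic``
    Bernoulli responses in a balanced randomized-blocks design with two
    treatments and four blocks,

        logit(mu_ik) = a0 + a_i + b_k + g_ik,

    default coefficients (a0, a2, b2, b3, b4, g22, g23, g24) =
    (-1, 1, 0, -1, 1, 0, 0, 0) — the interaction null holds.
``copula_nb``
    Correlated overdispersed counts: z_i ~ MVN(0, R) with AR(1)
    correlation, u_ij = Phi(z_ij), Y_ij = F^{-1}(u_ij; mu_ij, psi_j)
    with negative binomial marginals.  The mean matrix defaults to the
    main-effects (null) fit of the Tasmania copepod data, scaled by an
    abundance factor delta; cov(U_i) is constant across observations.
``poisson_lognormal``
    Same means and mean-variance relationship, but through a lognormal
    random effect: Y_ij ~ Poisson(m_ij),
    log m_ij = log mu_ij - sigma_j^2/2 + z_ij,
    z_i ~ MVN(0, S_d R S_d), sigma_j = sqrt(log(1 + psi_j)) so that
    Var(Y) = mu + (e^{sigma^2}-1) mu^2 = mu + psi mu^2.  Data are *not*
    marginally negative binomial and cov(U_i) varies with the mean —
    a deliberate, mild model violation.

Sample size and dimension are grown by replicating the design and mean
matrix (and tiling psi with the columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import tasmania_dataset
from .design import DesignSpec
from .families import family_quantile
from .marginal_models import fit_marginals
from .resampling import ResampleScheme
from .test_stats import bootstrap_test

__all__ = [
    "SimulationConfig",
    "sim_logistic_blocks",
    "ar1_correlation",
    "sim_copula_nb",
    "sim_poisson_lognormal",
    "tasmania_null_means",
    "type1_experiment",
    "ExperimentResult",
]

#: default logistic randomized-blocks coefficients
#: (a0, a2, b2, b3, b4, g22, g23, g24); interaction terms zero
LOGISTIC_COEFS = (-1.0, 1.0, 0.0, -1.0, 1.0, 0.0, 0.0, 0.0)


@dataclass
class SimulationConfig:
    """Settings for one simulation regime / experiment."""

    regime: str = "logistic"
    n: int = 64
    p: int = 1
    delta: float = 1.0
    rho: float = 0.7
    coefs: tuple = LOGISTIC_COEFS
    n_datasets: int = 300
    B: int = 300
    level: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.regime not in ("logistic", "copula_nb", "poisson_lognormal"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.delta <= 0:
            raise ValueError("abundance factor delta must be > 0")
        if not -1 < self.rho < 1:
            raise ValueError("AR(1) parameter rho must satisfy |rho| < 1")


def blocks_design_table(n: int, n_blocks: int = 4, n_treat: int = 2) -> pd.DataFrame:
    """Balanced treatment-within-block table with n/(blocks*treatments) replicates."""
    cell = n_blocks * n_treat
    if n % cell:
        raise ValueError(f"n={n} not divisible by the {cell} design cells")
    reps = n // cell
    blocks = [chr(ord("A") + k) for k in range(n_blocks)]
    treats = [f"t{i + 1}" for i in range(n_treat)]
    rows = [(t, b) for b in blocks for t in treats for _ in range(reps)]
    return pd.DataFrame(rows, columns=["treatment", "block"])


def sim_logistic_blocks(
    n: int,
    rng: np.random.Generator,
    coefs: tuple = LOGISTIC_COEFS,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Bernoulli randomized-blocks data; returns (n x 1 response, design table)."""
    table = blocks_design_table(n)
    a0, a2, b2, b3, b4, g22, g23, g24 = coefs
    alpha = {"t1": 0.0, "t2": a2}
    beta = {"A": 0.0, "B": b2, "C": b3, "D": b4}
    gamma = {("t2", "B"): g22, ("t2", "C"): g23, ("t2", "D"): g24}
    eta = np.array(
        [
            a0 + alpha[t] + beta[b] + gamma.get((t, b), 0.0)
            for t, b in zip(table["treatment"], table["block"])
        ]
    )
    mu = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.uniform(size=n) < mu).astype(float)
    return y[:, None], table


def logistic_cell_probability(treatment: str, block: str, coefs: tuple = LOGISTIC_COEFS) -> float:
    """Plug-in cell mean of the logistic randomized-blocks model."""
    a0, a2, b2, b3, b4, g22, g23, g24 = coefs
    alpha = {"t1": 0.0, "t2": a2}
    beta = {"A": 0.0, "B": b2, "C": b3, "D": b4}
    gamma = {("t2", "B"): g22, ("t2", "C"): g23, ("t2", "D"): g24}
    eta = a0 + alpha[treatment] + beta[block] + gamma.get((treatment, block), 0.0)
    return 1.0 / (1.0 + np.exp(-eta))


def ar1_correlation(p: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix R[j, k] = rho^|j - k|."""
    if not -1 < rho < 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@lru_cache(maxsize=1)
def tasmania_null_means() -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Fitted means and dispersions of the Tasmania main-effects NB model.

    Returns (mu 16 x 12, psi length 12, design table); the standard mean
    matrix that the count simulators replicate and rescale.
    """
    ds = tasmania_dataset()
    null = DesignSpec(ds.design_table, "block+treatment")
    fits = fit_marginals(ds.Y, null, "negative.binomial")
    return fits.mu, fits.psi, ds.design_table


def _replicate(mean_matrix: np.ndarray, psi: np.ndarray, n: int, p: int):
    """Tile the base mean matrix to n rows and p columns (psi tiles along)."""
    n0, p0 = mean_matrix.shape
    if n % n0 or p % p0:
        raise ValueError(f"n and p must be multiples of the base shape {n0} x {p0}")
    mu = np.tile(mean_matrix, (n // n0, p // p0))
    return mu, np.tile(psi, p // p0)


def sim_copula_nb(
    n: int,
    p: int,
    rng: np.random.Generator,
    mean_matrix: np.ndarray | None = None,
    psi: np.ndarray | None = None,
    delta: float = 1.0,
    rho: float = 0.7,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Gaussian-copula counts with negative binomial marginals."""
    if mean_matrix is None or psi is None:
        mu0, psi0, table0 = tasmania_null_means()
        mean_matrix = mu0 if mean_matrix is None else mean_matrix
        psi = psi0 if psi is None else psi
    mu, psi = _replicate(np.asarray(mean_matrix, float), np.asarray(psi, float), n, p)
    mu = delta * mu
    L = np.linalg.cholesky(ar1_correlation(p, rho))
    z = rng.standard_normal((n, p)) @ L.T
    u = stats.norm.cdf(z)
    Y = np.empty((n, p))
    for j in range(p):
        Y[:, j] = family_quantile(u[:, j], mu[:, j], psi[j], "negative.binomial")
    table = pd.concat([tasmania_null_means()[2]] * (n // 16), ignore_index=True)
    return Y, table


def sim_poisson_lognormal(
    n: int,
    p: int,
    rng: np.random.Generator,
    mean_matrix: np.ndarray | None = None,
    psi: np.ndarray | None = None,
    delta: float = 1.0,
    rho: float = 0.7,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Poisson counts with a correlated lognormal random effect.

    sigma_j = sqrt(log(1 + psi_j)) matches the negative binomial
    quadratic variance at the same mean; the -sigma^2/2 offset keeps
    E[Y] equal to the target mean.
    """
    if mean_matrix is None or psi is None:
        mu0, psi0, table0 = tasmania_null_means()
        mean_matrix = mu0 if mean_matrix is None else mean_matrix
        psi = psi0 if psi is None else psi
    mu, psi = _replicate(np.asarray(mean_matrix, float), np.asarray(psi, float), n, p)
    mu = delta * mu
    sigma = np.sqrt(np.log1p(psi))
    L = np.linalg.cholesky(ar1_correlation(p, rho))
    z = (rng.standard_normal((n, p)) @ L.T) * sigma[None, :]
    m = mu * np.exp(z - 0.5 * sigma[None, :] ** 2)
    Y = rng.poisson(m).astype(float)
    table = pd.concat([tasmania_null_means()[2]] * (n // 16), ignore_index=True)
    return Y, table


@dataclass
class ExperimentResult:
    """Rejection rates with their Monte-Carlo uncertainty."""

    table: pd.DataFrame
    p_values: dict[str, np.ndarray]
    config: SimulationConfig
    n_failed: dict[str, int] = field(default_factory=dict)


def _simulate_dataset(config: SimulationConfig, rng: np.random.Generator):
    if config.regime == "logistic":
        Y, table = sim_logistic_blocks(config.n, rng, config.coefs)
        family = "bernoulli"
    elif config.regime == "copula_nb":
        Y, table = sim_copula_nb(config.n, config.p, rng, delta=config.delta, rho=config.rho)
        family = "negative.binomial"
    else:
        Y, table = sim_poisson_lognormal(
            config.n, config.p, rng, delta=config.delta, rho=config.rho
        )
        family = "negative.binomial"
    return Y, table, family


def type1_experiment(
    config: SimulationConfig,
    schemes: list[str] | list[ResampleScheme],
    statistic: str | None = None,
) -> ExperimentResult:
    """Empirical type-I error of bootstrap interaction tests under H0.

    For each simulated dataset (interaction coefficients zero) and each
    scheme, runs a bootstrap test of block x treatment interaction and
    records the p-value; the rejection rate at ``config.level`` is
    reported with its binomial Monte-Carlo standard error.  Datasets on
    which a scheme fails are excluded and counted.
    """
    if statistic is None:
        statistic = "lr" if config.regime == "logistic" else "score"
    ss = np.random.SeedSequence(config.seed)
    data_seeds, test_seeds = ss.spawn(2)
    data_children = data_seeds.spawn(config.n_datasets)
    test_children = test_seeds.spawn(config.n_datasets)

    schemes = [s if isinstance(s, ResampleScheme) else ResampleScheme(s, B=config.B) for s in schemes]
    pvals: dict[str, list[float]] = {s.name: [] for s in schemes}
    n_failed: dict[str, int] = {s.name: 0 for s in schemes}

    for d in range(config.n_datasets):
        rng = np.random.default_rng(data_children[d])
        Y, table, family = _simulate_dataset(config, rng)
        null = DesignSpec(table, "block+treatment")
        alt = DesignSpec(table, "block*treatment")
        sub_seeds = test_children[d].spawn(len(schemes))
        for s, scheme, sd in zip(range(len(schemes)), schemes, sub_seeds):
            sc = ResampleScheme(
                scheme.name, B=scheme.B, rejitter=scheme.rejitter,
                rescale=scheme.rescale, corr_model=scheme.corr_model,
                seed=int(sd.generate_state(1)[0] % (2**31 - 1)),
            )
            try:
                res = bootstrap_test(Y, null, alt, family, sc, statistic=statistic)
                pvals[scheme.name].append(res.p_value)
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                n_failed[scheme.name] += 1

    rows = []
    out_p = {}
    for scheme in schemes:
        p = np.asarray(pvals[scheme.name])
        out_p[scheme.name] = p
        m = len(p)
        rate = float(np.mean(p <= config.level)) if m else np.nan
        se = float(np.sqrt(rate * (1 - rate) / m)) if m else np.nan
        rows.append(
            {
                "scheme": scheme.name,
                "regime": config.regime,
                "n": config.n,
                "p_vars": config.p,
                "delta": config.delta,
                "rho": config.rho,
                "n_datasets": m,
                "rejection_rate": rate,
                "mc_se": se,
                "level": config.level,
                "n_failed": n_failed[scheme.name],
            }
        )
    return ExperimentResult(pd.DataFrame(rows), out_p, config, n_failed)
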