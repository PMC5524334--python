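# Methods

## The problem

Regression models for discrete, multivariate responses — e.g. counts of
p species on n sites with a factorial design — need resampling-based
inference when p is not small relative to n or when the tested
hypothesis (an interaction) does not make observations exchangeable.
Residual resampling keeps the design fixed, but classical residuals
(Pearson, deviance) are not identically distributed for discrete data,
and resampling them produces values off the response support.

## PIT residuals

For an observation y with fitted marginal CDF F, the probability
integral transform residual is

    u = q F(y) + (1 - q) F(y-),    q ~ U(0, 1),

where F(y-) is the left CDF limit (F(y-1) on integer support) and the
jitter q spreads the point mass of y uniformly over its CDF step.  If
the marginal model is correct and evaluated at the true parameters, u
is exactly standard uniform, independently of the parameter values —
residuals are (asymptotically) pivotal, which is what makes them
resampleable.  z = Phi^{-1}(u) puts them on the normal scale for
diagnostics and correlation estimation.

## The PIT-trap bootstrap

1. Fit the null marginal model to each response variable.
2. Draw a jitter matrix and compute the n x p matrix of PIT residuals;
   optionally rescale (below).
3. For each resample: draw n row indices with replacement, take whole
   residual rows (preserving cross-variable dependence without
   modelling it), and invert each entry through the fitted marginal
   quantile function of its destination row.  For discrete families
   the inverse is the smallest support value y* with
   F(y*-) < u* <= F(y*), so resampled data always live on the support.
4. Recompute the test statistic on each resampled matrix.

By default the jitter and residuals are redrawn inside the resampling
loop (recommended for discrete data) and residuals are rescaled:
column j of z is divided by its sample standard deviation (denominator
n - 1), an empirical correction for the overfitting-induced shrinkage
of residual scale in small samples.  A `center` flag additionally
removes the column mean first (off by default; the rescaling display
divides only).  A zero-variance column keeps factor 1.

Competing schemes implemented for comparison:

* **parametric** — simulate the uniforms through a Gaussian copula
  with a supplied correlation (shrunk-unstructured, exchangeable, or
  identity) instead of resampling them; requires the joint correlation
  to be specified.
* **pearson** — resample rows of Pearson residuals and reconstruct
  y* = mu + sqrt(V) r*; counts are truncated below at 0 and kept
  non-integer, Bernoulli values truncated to [0, 1].  The truncation
  changes the mean-variance relationship — this comparator is
  implemented faithfully, pathologies included, and the scheme reports
  truncation counts.
* **case** — resample (design row, response row) pairs jointly; with
  2 replicates per cell in 16 rows a given cell is empty with
  probability (14/16)^16 ~ 0.118, so interaction designs frequently
  become rank-deficient (flagged; the statistic then uses the
  estimable subspace via a pseudo-inverse).

## Marginal models

* Negative binomial, log link, Var(Y) = mu + psi mu^2.  Maximum
  likelihood by IRLS on the coefficients nested in a 1-D Brent search
  over log psi (bounds 1e-8..1e4, xatol 1e-3 on the log scale; IRLS
  iteration cap 200, relative log-likelihood tolerance 1e-8, step
  halving on likelihood decrease).  If the profile peaks at the lower
  boundary the Poisson limit psi = 0 is returned and flagged.  The
  linear predictor is capped at +/-30 so all-zero cells under
  saturated designs yield finite fits instead of errors.
* Bernoulli, logit link, same IRLS backbone; quasi-separation
  (|eta| > 15) and boundary columns are flagged, the cap again keeps
  fits finite.  Fractional responses in [0, 1] are accepted in the
  Pearson-bootstrap refitting path, where the same log-likelihood
  expressions serve as working likelihoods.
* Gaussian (identity link, ML scale) exists for the classical
  continuous-data reductions: for iid-error models the PIT-trap
  coincides with raw-residual resampling, and under an iid null it
  reduces to resampling rows of y.

Fits were validated against statsmodels (Poisson IRLS coefficients to
1e-6; joint NB-2 ML log-likelihood and dispersion on the example data).

## The score statistic

The interaction test uses a GEE-type score statistic with a working
between-variable correlation.  Per variable j, with null-fitted means,
variance function V and mean derivative d = d mu/d eta:

    s_ij = d_ij (y_ij - mu_ij) / V_ij          (score residual)
    Xt_j = X1 - X0 (X0' W_j X0)^{-1} X0' W_j X1   (nuisance-adjusted
                                                   tested columns)
    U_j  = Xt_j' s_j                            (efficient score)

The stacked scores' covariance couples variables through a correlation
matrix R:

    Cov[(j,a),(j',b)] = R_jj' sum_i (d/sqrt(V))_ij (d/sqrt(V))_ij'
                         Xt_ija Xt_ij'b

and T = U' Cov^{-1} U.  With R = I this is exactly the sum of the p
univariate score statistics; it is invariant to variable order; a
rank-deficient tested block (case resampling) falls back to a
pseudo-inverse.

**Working correlation.** R is the correlation of normal-scale PIT
residuals under the null fit, linearly shrunk toward the identity:
R(lam) = lam I + (1 - lam) R_sample.  Two intensity policies exist:

* the default fixed light ridge `DEFAULT_RIDGE = 0.0878`.  This value
  was calibrated once so that the jitter-expected statistic on the
  Tasmania copepod example reproduces the published observed statistic
  (40.99) of the same test; it retains essentially all of the
  estimated correlation while guaranteeing positive definiteness even
  when p >= n.  p-values are insensitive to the third decimal of this
  constant.
* a leave-one-out Gaussian-likelihood estimator over the grid
  {0, 0.02, ..., 1} (`shrink_correlation` with `lam=None`).  It is
  well calibrated as an estimator (heavy shrinkage for independent
  residuals, light for strongly correlated ones, intensity bounded
  away from zero when p >= n) but selects heavy shrinkage on small
  jittered residual matrices, where jitter noise masks correlation;
  with it the statistic on the worked example would be ~29, far from
  the published value, so it is not the default for the test.

**Jitter handling.** The jitter makes any single evaluation of T
random (sd ~ 4 on the worked example).  The reported observed
statistic is therefore the average of the quadratic form over
`n_jitter_observed = 400` independent jitter draws (the score pieces
and CDF bounds are jitter-free and computed once, so this is cheap);
at 400 draws the run-to-run sd is ~0.25.  Resampled statistics use a
single jitter draw each (`n_jitter = 1`): the bootstrap null then
retains the spread of the routinely computed single-jitter statistic,
of which the averaged observed value estimates the centre.  Averaging
the resampled statistics as well tightens the null distribution and
systematically lowers p-values; both knobs are exposed.

The univariate logistic likelihood-ratio statistic 2(l_alt - l_null)
is provided for the randomized-blocks simulation; it involves no
jitter.

p-values use the Monte-Carlo-valid convention
p = (1 + #{T* >= T}) / (B + 1).  Resamples whose refit or statistic
fails are excluded and counted; more than 1% failures aborts the run.

## Simulators

* **logistic** — balanced 2-treatment x 4-block Bernoulli data,
  logit mu = a0 + a_i + b_k + g_ik with treatment-contrast
  identifiability (terms indexed by a reference level are zero);
  default coefficients (-1, 1, 0, -1, 1, 0, 0, 0), so the interaction
  null holds.
* **copula_nb** — z_i ~ MVN(0, R) with AR(1) R (default rho = 0.7),
  u = Phi(z), Y = F^{-1}(u) with negative binomial marginals.  The
  mean matrix is the main-effects NB fit to the embedded Tasmania data
  (fitted at run time), scaled by delta and replicated row/column-wise
  to reach larger n and p (dispersions tile with the columns).
  cov(U_i) is constant across observations.
* **poisson_lognormal** — Y ~ Poisson(m),
  log m = log(delta mu) - sigma^2/2 + z, z ~ MVN(0, S_d R S_d), with
  sigma_j = sqrt(log(1 + psi_j)) chosen so the lognormal mixture
  variance mu + (e^{sigma^2} - 1) mu^2 equals the NB quadratic
  variance at the same mean.  Data are deliberately *not* marginally
  NB (a GOF test rejects at large n) — the regime probes robustness to
  mild marginal misspecification.

What the generators do not emulate: real assemblages have
non-Gaussian dependence, varying cluster sizes, zero inflation beyond
the NB, and covariate measurement error; passing tests show the
machinery is correct under the stated models, not that the method is
robust to everything field data can do.

The type-I-error harness runs, per simulated dataset, a bootstrap
interaction test and reports the rejection rate at the nominal level
with its binomial Monte-Carlo standard error; per-dataset p-values are
kept.  The default experiment scale is 300 datasets x 300 resamples
(the full published grids used 1000 x 1000 per cell across many cells;
the reduced scale keeps a complete run in minutes while leaving Monte-
Carlo error small enough for calibration checks).  Every generator is
seed-reproducible; one RNG stream is spawned per resample index from
the master seed, so results do not depend on execution order.

## Numerical choices and degenerate inputs

* u clamped to (1e-12, 1 - 1e-12) before Phi^{-1} and before quantile
  inversion; u <= 0 maps to the minimum support value.
* psi < 1e-10 is evaluated on the Poisson branch of the CDF/quantile.
* Variance floors (1e-12) guard score weights where capped fits push
  means to ~e^{-30}; such variables contribute ~nothing to the
  statistic, which is the correct limit.
* Non-positive-definite correlation inputs to the copula are repaired
  by eigenvalue clipping (with a warning) and rescaled to unit
  diagonal.
* The exchangeable parametric variant uses the mean off-diagonal of
  the shrunk correlation as its common rho (the source did not state
  an estimator; documented as this package's choice).

## Known limitations

* The score-statistic construction is pinned to the published worked
  example through the ridge-intensity calibration; an independent
  implementation with different shrinkage would shift the statistic's
  scale (though much less so its p-values, since observed and
  resampled statistics move together).
* The PIT-trap assumes the marginal family is correctly specified;
  under misspecification residuals are no longer uniform and size can
  drift, as the Poisson-lognormal regime demonstrates at large p.
* Only two-way factorial formulas (main effects + one interaction) are
  parsed; offsets, continuous-by-factor interactions and other GLM
  families are out of scope.
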