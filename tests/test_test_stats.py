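"""Score statistic, shrunk correlation, LR statistic and bootstrap p-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pittrap import (
    DesignSpec,
    ResampleScheme,
    ShrunkCorrelation,
    bootstrap_test,
    fit_marginals,
    lr_statistic_logistic,
    score_statistic,
    score_test_statistic,
    shrink_correlation,
)
from pittrap.simulators import sim_logistic_blocks


class TestShrinkCorrelation:
    def test_full_shrink_is_identity(self, rng):
        z = rng.standard_normal((20, 4))
        out = shrink_correlation(z, lam=1.0)
        assert np.array_equal(out.R, np.eye(4))

    def test_no_shrink_perfect_correlation_flagged_singular(self, rng):
        x = rng.standard_normal(30)
        z = np.column_stack([x, 2 * x])
        out = shrink_correlation(z, lam=0.0)
        assert out.R[0, 1] == pytest.approx(1.0)
        assert out.singular

    def test_estimated_intensity_high_dimension(self):
        # n << p: the LOO likelihood must bound lambda away from 0 and
        # return a positive definite matrix
        rng = np.random.default_rng(17)
        z = rng.standard_normal((16, 60))
        out = shrink_correlation(z)
        assert out.lam > 0.05
        assert np.linalg.eigvalsh(out.R).min() > 0

    def test_estimator_tracks_true_dependence(self):
        # strong true correlation at decent n: little shrinkage;
        # independent data: heavy shrinkage
        from pittrap.simulators import ar1_correlation

        rng = np.random.default_rng(3)
        L = np.linalg.cholesky(ar1_correlation(12, 0.7))
        lam_dep = shrink_correlation(rng.standard_normal((160, 12)) @ L.T).lam
        lam_ind = shrink_correlation(rng.standard_normal((160, 12))).lam
        assert lam_dep < 0.15
        assert lam_ind > 0.5

    def test_single_variable(self):
        out = shrink_correlation(np.random.default_rng(0).standard_normal((10, 1)))
        assert out.R.shape == (1, 1) and out.lam == 1.0


class TestScoreStatistic:
    def test_zero_when_scores_vanish(self, tas_null, tas_alt):
        # constant responses are fitted exactly by the null model, so
        # the tested-term scores are identically zero
        Y = np.full((16, 3), 7.0)
        fits = fit_marginals(Y, tas_null, "negative.binomial")
        T = score_statistic(Y, tas_null, tas_alt, fits, np.eye(3))
        assert T == pytest.approx(0.0, abs=1e-8)

    def test_identity_correlation_separates(self, tasmania, tas_null, tas_alt, tas_fits):
        T, per_var = score_statistic(
            tasmania.Y, tas_null, tas_alt, tas_fits, np.eye(12), return_per_variable=True
        )
        assert T == pytest.approx(per_var.sum(), rel=1e-8)

    def test_invariant_to_variable_order(self, tasmania, tas_null, tas_alt, tas_fits, rng):
        from pittrap import compute_pit, to_normal_scale

        z = to_normal_scale(compute_pit(tasmania.Y, tas_fits, rng=rng))
        R = shrink_correlation(z, lam=0.09)
        T1 = score_statistic(tasmania.Y, tas_null, tas_alt, tas_fits, R)
        perm = rng.permutation(12)
        from pittrap.marginal_models import MarginalFitSet

        fits_p = MarginalFitSet(
            [tas_fits.fits[j] for j in perm], tas_fits.design, tas_fits.family
        )
        Rp = ShrunkCorrelation(R.R[np.ix_(perm, perm)], R.lam)
        T2 = score_statistic(tasmania.Y[:, perm], tas_null, tas_alt, fits_p, Rp)
        assert T2 == pytest.approx(T1, rel=1e-4)

    def test_univariate_matches_partitioned_information_oracle(self):
        # p = 1 logistic score test against the textbook partitioned
        # formula U_g' (I_gg - I_gb I_bb^-1 I_bg)^-1 U_g on 8 points
        df = pd.DataFrame({"g": ["a", "a", "a", "a", "b", "b", "b", "b"]})
        null = DesignSpec(df, "1")
        alt = DesignSpec(df, "g")
        y = np.array([0.0, 0, 1, 0, 1, 1, 1, 0])
        fits = fit_marginals(y, null, "bernoulli")
        T = score_statistic(y, null, alt, fits, np.ones((1, 1)))

        X = alt.matrix
        mu = fits[0].mu
        W = mu * (1 - mu)
        U_full = X.T @ (y - mu)
        info = X.T @ (X * W[:, None])
        I00, I01, I11 = info[0, 0], info[0, 1], info[1, 1]
        eff = I11 - I01**2 / I00
        expect = U_full[1] ** 2 / eff
        assert T == pytest.approx(expect, rel=1e-6)

    def test_jitter_averaged_statistic_is_stable(self, tasmania, tas_null, tas_alt, tas_fits):
        Ts = [
            score_test_statistic(
                tasmania.Y, tas_null, tas_alt, tas_fits,
                rng=np.random.default_rng(s), n_jitter=200,
            )
            for s in (0, 1)
        ]
        assert abs(Ts[0] - Ts[1]) < 1.5


class TestLRStatistic:
    def _designs(self, n):
        _, table = sim_logistic_blocks(n, np.random.default_rng(0))
        return DesignSpec(table, "block+treatment"), DesignSpec(table, "block*treatment")

    def test_identical_designs_give_zero(self):
        null, _ = self._designs(16)
        y = np.random.default_rng(1).integers(0, 2, 16).astype(float)
        assert lr_statistic_logistic(y, null, null) == 0.0

    def test_two_group_closed_form(self):
        # 2-group logistic LR has a closed binomial form
        df = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10})
        null, alt = DesignSpec(df, "1"), DesignSpec(df, "g")
        y = np.array([1.0] * 3 + [0.0] * 7 + [1.0] * 7 + [0.0] * 3)

        def bern_ll(k, n, p):
            return k * np.log(p) + (n - k) * np.log(1 - p)

        ll_null = bern_ll(10, 20, 0.5)
        ll_alt = bern_ll(3, 10, 0.3) + bern_ll(7, 10, 0.7)
        expect = 2 * (ll_alt - ll_null)
        assert lr_statistic_logistic(y, null, alt) == pytest.approx(expect, abs=1e-6)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        y, table = sim_logistic_blocks(64, rng)
        null = DesignSpec(table, "block+treatment")
        alt = DesignSpec(table, "block*treatment")
        ours = lr_statistic_logistic(y[:, 0], null, alt)
        l0 = sm.Logit(y[:, 0], null.matrix).fit(disp=0).llf
        l1 = sm.Logit(y[:, 0], alt.matrix).fit(disp=0).llf
        assert ours == pytest.approx(2 * (l1 - l0), abs=1e-5)

    def test_null_distribution_is_chi2_3(self):
        # large-n LR for the 2x4 interaction is approximately chi^2_3
        rng = np.random.default_rng(8)
        stats_lr = np.empty(2000)
        for i in range(2000):
            y, table = sim_logistic_blocks(512, rng)
            null = DesignSpec(table, "block+treatment")
            alt = DesignSpec(table, "block*treatment")
            stats_lr[i] = lr_statistic_logistic(y[:, 0], null, alt)
        u = stats.chi2.cdf(stats_lr, 3)
        ks = stats.kstest(u, "uniform").statistic
        assert ks < 1.63 / np.sqrt(2000)  # 1% critical value


class TestBootstrapTest:
    def test_pvalue_floor_when_statistic_dominates(self):
        # gigantic interaction effect: observed LR exceeds every null
        # resample, so the p-value hits its Monte-Carlo floor
        rng = np.random.default_rng(2)
        _, table = sim_logistic_blocks(64, rng)
        # XOR-type pattern: not linearly separable by main effects
        hi = (
            (table["treatment"] == "t2") & table["block"].isin(["C", "D"])
        ) | ((table["treatment"] == "t1") & table["block"].isin(["A", "B"]))
        eta = np.where(hi, 4.0, -4.0)
        y = (rng.uniform(size=64) < 1 / (1 + np.exp(-eta))).astype(float)[:, None]
        null = DesignSpec(table, "block+treatment")
        alt = DesignSpec(table, "block*treatment")
        res = bootstrap_test(
            y, null, alt, "bernoulli", ResampleScheme("pit.trap", B=49, seed=0),
            statistic="lr",
        )
        assert res.statistic > np.nanmax(res.stat_star)
        assert res.p_value == pytest.approx(1.0 / 50.0)

    def test_pvalue_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        T = 3.0
        T_star = rng.exponential(size=99)
        p1 = (1 + np.sum(T_star >= T)) / 100
        p2 = (1 + np.sum(np.exp(T_star) >= np.exp(T))) / 100
        assert p1 == p2

    def test_uniform_pvalues_under_null(self):
        # logistic interaction truly absent: bootstrap p-values are
        # approximately U(0,1)
        rng = np.random.default_rng(31)
        n_sets, B = 120, 99
        pvals = np.empty(n_sets)
        for i in range(n_sets):
            y, table = sim_logistic_blocks(64, rng)
            null = DesignSpec(table, "block+treatment")
            alt = DesignSpec(table, "block*treatment")
            seed = int(rng.integers(2**31 - 1))
            res = bootstrap_test(
                y, null, alt, "bernoulli",
                ResampleScheme("pit.trap", B=B, seed=seed), statistic="lr",
            )
            pvals[i] = res.p_value
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_case_scheme_handles_rank_deficiency(self, tasmania, tas_null, tas_alt):
        res = bootstrap_test(
            tasmania.Y, tas_null, tas_alt, "negative.binomial",
            ResampleScheme("case", B=40, seed=3), max_failed_frac=0.2,
        )
        assert res.n_valid >= 32
        assert np.isfinite(res.statistic)
        assert res.flags.get("empty_cell", 0) > 0

    def test_exchangeable_parametric_runs(self, tasmania, tas_null, tas_alt):
        res = bootstrap_test(
            tasmania.Y, tas_null, tas_alt, "negative.binomial",
            ResampleScheme("parametric", B=30, seed=1, corr_model="exchangeable"),
        )
        assert 0 < res.p_value <= 1
        from pittrap import DEFAULT_RIDGE

        assert res.lam == pytest.approx(DEFAULT_RIDGE)

    def test_rejects_bad_arguments(self, tasmania, tas_null, tas_alt):
        with pytest.raises(ValueError):
            bootstrap_test(tasmania.Y, tas_null, tas_alt, statistic="wald")
        with pytest.raises(ValueError):
            bootstrap_test(tasmania.Y, tas_null, tas_alt, statistic="lr")
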