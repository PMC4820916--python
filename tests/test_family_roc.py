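"""Liability-threshold prevalence and the family-data ROC construction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from lipidrisk import (
    bayes_sens_spec,
    compare_aucs,
    empirical_roc,
    estimate_prevalence,
    roc_curve,
)
from lipidrisk.roc import (
    auc_correlation_bootstrap,
    auc_hanley,
    hanley_mcneil_se,
    youden_cutoff,
)
from lipidrisk.liability import LiabilityThreshold


def make_binary_data(n, signal, seed, h2=0.0, R=None):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    if R is not None and h2 > 0:
        L = np.linalg.cholesky(R + 1e-9 * np.eye(n))
        g = np.sqrt(h2) * (L @ rng.normal(size=n))
    else:
        g = 0.0
    liab = signal * x + g + np.sqrt(max(1 - h2, 1e-12)) * rng.normal(size=n)
    y = (liab > 0.5).astype(int)
    return y, x


class TestBayesSensSpec:
    def test_perfect_marker(self):
        assert bayes_sens_spec(0.5, 1.0, 0.0) == pytest.approx((1.0, 1.0))

    def test_uninformative_marker(self):
        assert bayes_sens_spec(0.5, 0.3, 0.3) == pytest.approx((0.5, 0.5))

    def test_printed_formula_evaluation(self):
        sens, spec = bayes_sens_spec(0.3, 0.4, 0.1)
        assert sens == pytest.approx(0.3 * 0.4 / (0.3 * 0.4 + 0.7 * 0.1))
        assert spec == pytest.approx(0.7 * 0.9 / (0.7 * 0.9 + 0.3 * 0.6))
        assert (sens, spec) == pytest.approx((0.6316, 0.7778), abs=1e-4)

    def test_reconstructs_two_by_two_table(self):
        """With exact subgroup prevalences the Bayesian inversion returns the
        empirical sensitivity/specificity (algebraic identity)."""
        rng = np.random.default_rng(3)
        y = (rng.random(400) < 0.3).astype(int)
        x = rng.normal(size=400) + y
        for c in np.quantile(x, [0.2, 0.5, 0.8]):
            above = x > c
            p, p1, p0 = above.mean(), y[above].mean(), y[~above].mean()
            sens, spec = bayes_sens_spec(p, p1, p0)
            assert sens == pytest.approx(np.mean(x[y == 1] > c))
            assert spec == pytest.approx(np.mean(x[y == 0] <= c))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bayes_sens_spec(1.2, 0.5, 0.5)
        with pytest.raises(ZeroDivisionError):
            bayes_sens_spec(0.4, 0.0, 0.0)  # no implied cases: sens is 0/0


class TestLiabilityModel:
    def test_prevalence_is_case_fraction_without_covariates(self):
        rng = np.random.default_rng(0)
        y = (rng.random(2000) < 0.21).astype(int)
        fit = estimate_prevalence(y)
        assert abs(fit.prevalence - y.mean()) < 1e-10

    def test_threshold_zero_at_half_prevalence(self):
        y = np.array([0, 1] * 100)
        assert estimate_prevalence(y).mu == pytest.approx(0.0, abs=1e-9)

    def test_h2_zero_matches_probit_oracle(self):
        y, x = make_binary_data(500, signal=0.8, seed=1)
        fit = LiabilityThreshold(y, exog=x[:, None], kinship=np.eye(500)).fit(heritability=0.0)
        oracle = sm.Probit(y, sm.add_constant(x)).fit(disp=False)
        assert fit.mu == pytest.approx(oracle.params[0], abs=1e-6)
        assert fit.beta[0] == pytest.approx(oracle.params[1], abs=1e-6)

    def test_degenerate_subset_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            fit = estimate_prevalence(np.ones(50, dtype=int))
        assert 0 < fit.prevalence < 1 and fit.degenerate

    def test_polygenic_fit_recovers_prevalence_in_families(self):
        # block-diagonal sibships of size 4
        n_fam, fam_size = 60, 4
        n = n_fam * fam_size
        R = np.kron(np.eye(n_fam), np.full((fam_size, fam_size), 0.5))
        np.fill_diagonal(R, 1.0)
        y, x = make_binary_data(n, signal=0.0, seed=5, h2=0.6, R=R)
        fit = LiabilityThreshold(y, kinship=R).fit()
        assert abs(fit.prevalence - y.mean()) < 0.08
        assert 0 <= fit.heritability <= 0.9


class TestRocCurve:
    def test_matches_empirical_roc_on_unrelated_data(self):
        y, x = make_binary_data(600, signal=1.0, seed=2)
        fam = roc_curve(y, x)
        # pointwise oracle at the same cutoffs
        for c, s, sp in zip(fam.cutoffs, fam.sensitivity, fam.specificity):
            assert s == pytest.approx(np.mean(x[y == 1] > c), abs=0.02)
            assert sp == pytest.approx(np.mean(x[y == 0] <= c), abs=0.02)
        emp = empirical_roc(y, x)
        assert abs(fam.auc - emp.auc) < 0.01

    def test_null_predictor_auc_near_half(self):
        y, x = make_binary_data(800, signal=0.0, seed=4)
        fam = roc_curve(y, x)
        assert abs(fam.auc - 0.5) < 3 * fam.auc_se

    def test_liability_predictor_gives_high_auc(self):
        rng = np.random.default_rng(6)
        liab = rng.normal(size=1500)
        y = (liab > 1.0).astype(int)
        noisy = liab + 0.3 * rng.normal(size=1500)
        fam = roc_curve(y, noisy)
        assert fam.auc > 0.9

    def test_too_few_distinct_values_rejected(self):
        y = np.array([0, 1] * 20)
        with pytest.raises(ValueError, match="distinct"):
            roc_curve(y, np.tile([1.0, 2.0, 3.0, 4.0], 10))

    def test_cutoff_grid_capped(self):
        y, x = make_binary_data(3000, signal=1.0, seed=7)
        fam = roc_curve(y, x, max_cutoffs=50)
        assert len(fam.cutoffs) <= 50


class TestAucMachinery:
    def test_perfect_separation_auc_one(self):
        y = np.array([0] * 40 + [1] * 40)
        x = np.concatenate([np.zeros(40), np.ones(40) + 1])
        assert empirical_roc(y, x).auc == pytest.approx(1.0)

    def test_hanley_se_closed_form(self):
        # A=0.5 -> Q1=Q2=1/3; var=(0.25 + 49/12 + 49/12)/2500
        expected = np.sqrt((0.25 + 49 * (1 / 3 - 0.25) * 2) / 2500)
        assert hanley_mcneil_se(0.5, 50, 50) == pytest.approx(expected, rel=1e-12)

    def test_se_decreases_with_n(self):
        assert hanley_mcneil_se(0.75, 200, 200) < hanley_mcneil_se(0.75, 50, 50)

    def test_auc_hanley_consistent_with_curve(self):
        y, x = make_binary_data(400, signal=1.0, seed=8)
        fam = roc_curve(y, x)
        auc, se = auc_hanley(fam)
        assert auc == pytest.approx(fam.auc)
        assert se == pytest.approx(fam.auc_se)

    def test_compare_aucs_examples(self):
        chi2, p = compare_aucs(0.7, 0.05, 0.7, 0.05)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)
        chi2, p = compare_aucs(0.75, 0.03, 0.60, 0.03, correlation=0.0)
        z = 0.15 / np.sqrt(2 * 0.03**2)
        assert chi2 == pytest.approx(z**2)
        assert p == pytest.approx(stats.chi2.sf(z**2, 1))
        assert p == pytest.approx(4.1e-4, abs=2e-5)
        # symmetric in argument order
        assert compare_aucs(0.6, 0.04, 0.8, 0.05)[1] == compare_aucs(0.8, 0.05, 0.6, 0.04)[1]

    def test_compare_aucs_invalid_se(self):
        with pytest.raises(ValueError):
            compare_aucs(0.7, 0.0, 0.6, 0.05)

    def test_auc_correlation_bootstrap_bounds(self):
        rng = np.random.default_rng(10)
        y = (rng.random(300) < 0.3).astype(int)
        x = rng.normal(size=300) + y
        # a predictor correlates strongly with itself plus small noise,
        # weakly with an independent one
        r_self = auc_correlation_bootstrap(y, x, x + 0.05 * rng.normal(size=300), seed=1)
        r_indep = auc_correlation_bootstrap(y, x, rng.normal(size=300), seed=1)
        assert r_self > 0.9
        assert abs(r_indep) < 0.5

    def test_youden_cutoff_sensible(self):
        y, x = make_binary_data(600, signal=1.5, seed=9)
        fam = roc_curve(y, x)
        c = youden_cutoff(fam)
        assert np.min(x) < c < np.max(x)
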