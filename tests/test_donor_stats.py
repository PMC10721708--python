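"""Donor-effect statistics: closed forms vs independent oracles.

The REML/boundary-LRT closed forms are checked against frozen values from
R's lmerTest (lmer + ranova) computed on the same grids; the ANOVA closed
forms are checked against statsmodels' anova_lm on random tables.
"""

import numpy as np
import pytest
from scipy import stats

from deformcyte.donor_stats import (anova_class_difference, anova_donor_fixed,
                                    halved_chi2_p, lrt_random_effect)

# 6x3 balanced grid, numpy PCG64(20240917): donor sd 0.03, fold sd 0.02,
# residual sd 0.015 around 0.85 (interior REML optimum).
GRID_INTERIOR = np.array([
    [0.9115149224, 0.8404378714, 0.8011711231],
    [0.8785001627, 0.8446299070, 0.7617143725],
    [0.8542280607, 0.8340161682, 0.7821156009],
    [0.8597246107, 0.8401756061, 0.8406197572],
    [0.8288957493, 0.7903619659, 0.7895616212],
    [0.8987223604, 0.8667529048, 0.8210893776],
])
# lmerTest oracle for GRID_INTERIOR: lmer(acc ~ donor + (1|fold), REML)
LMER_INTERIOR = {"sigma2_A": 0.001236735, "sigma2": 0.0004756872,
                 "lrt": 9.752114, "p_unhalved": 0.001791166}
# lm anova oracle for the same grid
LM_ANOVA_INTERIOR = {"F": 0.8196, "p": 0.5586}


class TestLrtRandomEffect:
    def test_matches_lmer_oracle(self):
        mm = lrt_random_effect(GRID_INTERIOR)
        assert mm.sigma2_A == pytest.approx(LMER_INTERIOR["sigma2_A"], rel=1e-5)
        assert mm.sigma2 == pytest.approx(LMER_INTERIOR["sigma2"], rel=1e-5)
        assert mm.lrt == pytest.approx(LMER_INTERIOR["lrt"], rel=1e-6)
        assert mm.p_boundary == pytest.approx(
            LMER_INTERIOR["p_unhalved"] / 2, rel=1e-5)

    def test_zero_lrt_gives_half(self):
        assert halved_chi2_p(0.0) == pytest.approx(0.5)

    def test_boundary_estimate_when_fold_variance_absent(self):
        """MS_fold < MS_resid forces the variance estimate to the edge."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            acc = 0.9 + rng.normal(0, 0.02, (8, 4))
            acc -= acc.mean(axis=0, keepdims=True)   # kill fold contrasts
            acc += 0.9
            mm = lrt_random_effect(acc)
            assert mm.sigma2_A == 0.0
            assert mm.lrt >= 0.0 and mm.p_boundary == pytest.approx(0.5)

    def test_boundary_simulation_pileup(self):
        """Under sigma_A^2 = 0 the estimate piles up at zero in roughly
        half of replicates (exactly P(F(3,93) < 1) = 0.60 for the 32x4
        design) and p never exceeds 0.5."""
        rng = np.random.default_rng(1)
        zeros = 0
        n_rep = 300
        for _ in range(n_rep):
            acc = rng.normal(0.9, 0.03, (32, 4))
            mm = lrt_random_effect(acc)
            assert 0.0 <= mm.p_boundary <= 0.5
            assert mm.sigma2_A >= 0.0
            zeros += mm.sigma2_A == 0.0
        assert 0.50 < zeros / n_rep < 0.72

    def test_reml_profile_stationarity(self):
        """Interior optimum: the restricted likelihood is stationary in
        sigma_A^2; boundary optimum: one-sided derivative is negative."""
        from deformcyte.donor_stats import _reml_loglik

        def ll(acc, s2a, s2):
            D, F = acc.shape
            grand = acc.mean()
            col = acc.mean(axis=0)
            row = acc.mean(axis=1)
            ssf = D * ((col - grand) ** 2).sum()
            ssr = ((acc - row[:, None] - col[None, :] + grand) ** 2).sum()
            return _reml_loglik(ssf, ssr, F - 1, (D - 1) * (F - 1),
                                s2 + D * s2a, s2)

        mm = lrt_random_effect(GRID_INTERIOR)
        assert mm.sigma2_A > 0
        h = 1e-7
        d = (ll(GRID_INTERIOR, mm.sigma2_A + h, mm.sigma2)
             - ll(GRID_INTERIOR, mm.sigma2_A - h, mm.sigma2)) / (2 * h)
        assert abs(d) < 1e-2

        rng = np.random.default_rng(3)
        acc = rng.normal(0.9, 0.02, (10, 4))
        acc = acc - acc.mean(axis=0, keepdims=True) + 0.9
        mmb = lrt_random_effect(acc)
        assert mmb.sigma2_A == 0.0
        d1 = (ll(acc, h, mmb.sigma2) - ll(acc, 0.0, mmb.sigma2)) / h
        assert d1 <= 0

    def test_unbalanced_grid_refused(self):
        bad = GRID_INTERIOR.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="balanced"):
            lrt_random_effect(bad)


class TestAnovaDonorFixed:
    def test_matches_lm_oracle(self):
        an = anova_donor_fixed(GRID_INTERIOR)
        assert an.f_stat == pytest.approx(LM_ANOVA_INTERIOR["F"], abs=1e-4)
        assert an.p_value == pytest.approx(LM_ANOVA_INTERIOR["p"], abs=1e-4)
        assert an.df == [5, 12]

    def test_df_structure_32x4(self):
        rng = np.random.default_rng(2)
        an = anova_donor_fixed(rng.normal(0.9, 0.02, (32, 4)))
        assert an.df == [31, 96]

    def test_matches_statsmodels_on_random_tables(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(4)
        for _ in range(5):
            D, F = int(rng.integers(3, 10)), int(rng.integers(2, 6))
            acc = rng.normal(0.8, 0.05, (D, F))
            an = anova_donor_fixed(acc)
            df = pd.DataFrame({
                "acc": acc.ravel(),
                "donor": np.repeat([f"d{i}" for i in range(D)], F)})
            tab = sm.stats.anova_lm(ols("acc ~ C(donor)", df).fit())
            assert an.f_stat == pytest.approx(tab["F"].iloc[0], rel=1e-8)
            assert an.p_value == pytest.approx(tab["PR(>F)"].iloc[0], rel=1e-8)
            assert an.ss[0] == pytest.approx(tab["sum_sq"].iloc[0], rel=1e-8)
            assert an.ss[1] == pytest.approx(tab["sum_sq"].iloc[1], rel=1e-8)

    def test_degenerate_zero_residual(self):
        acc = np.array([[0.8, 0.8], [0.9, 0.9], [1.0, 1.0]])
        an = anova_donor_fixed(acc)
        assert an.degenerate
        assert np.isinf(an.f_stat) and an.p_value == 0.0
        assert an.ss[1] == 0.0

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError, match="2 folds"):
            anova_donor_fixed(np.ones((5, 1)))


class TestAnovaClassDifference:
    def test_df_structure(self):
        rng = np.random.default_rng(5)
        means = rng.normal(0.9, 0.02, 32)
        classes = np.array(["adult"] * 19 + ["fetal"] * 13)
        an = anova_class_difference(means, classes)
        assert an.df == [1, 30]

    def test_identical_class_means_give_zero_f(self):
        means = np.array([0.8, 0.9, 0.8, 0.9])
        classes = np.array(["adult", "adult", "fetal", "fetal"])
        an = anova_class_difference(means, classes)
        assert an.f_stat == pytest.approx(0.0)
        assert an.p_value == pytest.approx(1.0)

    def test_equals_squared_pooled_t(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            na, nf = int(rng.integers(3, 12)), int(rng.integers(3, 12))
            means = np.concatenate([rng.normal(0.88, 0.02, na),
                                    rng.normal(0.90, 0.02, nf)])
            classes = np.array(["adult"] * na + ["fetal"] * nf)
            an = anova_class_difference(means, classes)
            t = stats.ttest_ind(means[:na], means[na:], equal_var=True)
            assert an.f_stat == pytest.approx(t.statistic ** 2, rel=1e-9)
            assert an.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_class_difference([0.9, 0.8, 0.85],
                                   ["adult", "adult", "fetal"])


try:
    from hypothesis import given, settings, strategies as st
    from hypothesis.extra.numpy import arrays

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        acc=st.integers(3, 12).flatmap(lambda d: st.integers(2, 6).flatmap(
            lambda f: arrays(np.float64, (d, f),
                             elements=st.floats(0.5, 1.0, width=16)))))
    def test_invariants_hold_on_arbitrary_balanced_grids(acc):
        """Property: p_boundary in [0, 0.5], sigma_A^2 >= 0, LRT >= 0, and
        the donor-ANOVA sums of squares decompose the total, for any
        balanced accuracy grid."""
        mm = lrt_random_effect(acc)
        assert 0.0 <= mm.p_boundary <= 0.5
        assert mm.sigma2_A >= 0.0 and mm.lrt >= 0.0
        an = anova_donor_fixed(acc)
        ss_total = float(((acc - acc.mean()) ** 2).sum())
        assert abs(an.ss[0] + an.ss[1] - ss_total) < 1e-9 + 1e-9 * ss_total
except ImportError:      # hypothesis is an optional test dependency
    pass


def test_ss_decomposition_on_random_tables():
    """SS_total = SS_between + SS_within to 1e-10 on balanced tables."""
    rng = np.random.default_rng(7)
    for _ in range(10):
        D, F = int(rng.integers(3, 20)), int(rng.integers(2, 8))
        acc = rng.normal(0.8, 0.1, (D, F))
        an = anova_donor_fixed(acc)
        ss_total = float(((acc - acc.mean()) ** 2).sum())
        assert an.ss[0] + an.ss[1] == pytest.approx(ss_total, abs=1e-10)
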