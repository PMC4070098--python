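"""Association statistics: F ratios, parametric p-values, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy import stats as sps

from adaperm import (
    StatisticSpec,
    additive_regression_f,
    anova_pvalues,
    oneway_anova_f,
    parametric_pvalue,
    statistic_spec,
)


class TestOnewayAnova:
    def test_hand_computed_sums_of_squares(self):
        # groups (1,2), (3,4), (5,6): SSB=16 (df 2), SSW=1.5 (df 3) -> F=16
        y = np.array([1.0, 2, 3, 4, 5, 6])
        g = np.array([0, 0, 1, 1, 2, 2])
        assert oneway_anova_f(y, g) == pytest.approx(16.0, rel=1e-12)

    def test_matches_scipy_f_oneway(self, rng):
        for _ in range(10):
            g = rng.integers(0, 3, 30)
            y = rng.standard_normal(30)
            groups = [y[g == v] for v in np.unique(g)]
            expected = sps.f_oneway(*groups).statistic
            assert oneway_anova_f(y, g) == pytest.approx(expected, rel=1e-9)

    def test_equal_group_means_give_zero(self):
        y = np.array([1.0, 2, 1, 2, 1, 2])
        g = np.array([0, 0, 1, 1, 2, 2])
        assert oneway_anova_f(y, g) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_is_untestable(self):
        assert np.isnan(oneway_anova_f(np.arange(6.0), np.zeros(6)))

    def test_constant_trait_is_untestable(self):
        assert np.isnan(oneway_anova_f(np.ones(6), np.array([0, 0, 1, 1, 2, 2])))

    def test_zero_residual_variance_gives_inf(self):
        y = np.array([1.0, 1, 2, 2, 3, 3])
        g = np.array([0, 0, 1, 1, 2, 2])
        assert oneway_anova_f(y, g) == np.inf

    def test_two_classes_equal_squared_pooled_t(self, rng):
        g = np.array([0] * 12 + [1] * 8)
        y = rng.standard_normal(20)
        t = sps.ttest_ind(y[g == 0], y[g == 1], equal_var=True).statistic
        assert oneway_anova_f(y, g) == pytest.approx(t**2, rel=1e-9)

    def test_missing_entries_dropped_pairwise(self, rng):
        y = rng.standard_normal(20)
        g = rng.integers(0, 3, 20).astype(float)
        y_miss, g_miss = y.copy(), g.copy()
        y_miss[3] = np.nan
        g_miss[7] = -1  # missing-genotype sentinel
        keep = np.ones(20, bool)
        keep[[3, 7]] = False
        assert oneway_anova_f(y_miss, g_miss) == pytest.approx(
            oneway_anova_f(y[keep], g[keep]), rel=1e-12
        )


class TestAdditiveRegression:
    def test_closed_form_r_squared(self):
        y = np.array([0.0, 1, 2, 1, 3, 2])
        s = np.array([0.0, 0, 1, 1, 2, 2])
        r2 = np.corrcoef(y, s)[0, 1] ** 2
        expected = (len(y) - 2) * r2 / (1 - r2)
        assert additive_regression_f(y, s) == pytest.approx(expected, rel=1e-9)

    def test_perfect_fit_gives_inf(self):
        s = np.array([0.0, 1, 2, 1, 0])
        assert additive_regression_f(s.copy(), s) == np.inf

    def test_orthogonal_trait_gives_zero(self):
        s = np.array([0.0, 0, 1, 1, 2, 2])
        y = np.array([-1.0, 1, -1, 1, -1, 1])  # zero covariance with s
        assert additive_regression_f(y, s) == pytest.approx(0.0, abs=1e-12)

    def test_constant_dosage_untestable(self):
        assert np.isnan(additive_regression_f(np.arange(5.0), np.ones(5)))


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    shift=st.floats(-50, 50, allow_nan=False),
    scale=st.floats(0.01, 100, allow_nan=False),
    seed=st.integers(0, 1000),
)
def test_statistics_invariant_to_trait_location_scale(shift, scale, seed):
    """Adding a constant or positively rescaling y leaves both F values unchanged."""
    r = np.random.default_rng(seed)
    g = r.integers(0, 3, 25)
    if np.unique(g).size < 2:
        g[0], g[1] = 0, 1
    y = r.standard_normal(25)
    y2 = shift + scale * y
    assert oneway_anova_f(y2, g) == pytest.approx(oneway_anova_f(y, g), rel=1e-6, abs=1e-9)
    assert additive_regression_f(y2, g) == pytest.approx(
        additive_regression_f(y, g), rel=1e-6, abs=1e-9
    )


class TestParametricPvalue:
    def test_boundaries(self):
        spec = StatisticSpec("oneway_anova", 2, 10)
        assert parametric_pvalue(0.0, spec) == pytest.approx(1.0)
        assert parametric_pvalue(1e6, spec) < 1e-8
        assert parametric_pvalue(float("inf"), spec) == 0.0

    def test_matches_quadrature(self):
        spec = StatisticSpec("oneway_anova", 1, 10)
        expected, _ = integrate.quad(lambda x: sps.f.pdf(x, 1, 10), 4.0, np.inf)
        assert parametric_pvalue(4.0, spec) == pytest.approx(expected, rel=1e-6)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            StatisticSpec("oneway_anova", 0, 10)

    def test_spec_reflects_observed_classes(self):
        y = np.arange(8.0)
        g = np.array([0, 0, 0, 0, 2, 2, 2, 2])  # heterozygote class absent
        spec = statistic_spec("oneway_anova", y, g)
        assert (spec.df1, spec.df2) == (1, 6)


class TestVectorisedAnova:
    def test_agrees_with_scalar_route(self, rng):
        G = rng.integers(0, 3, size=(40, 12)).astype(float)
        G[3, 2] = -1  # one missing genotype
        G[:, 5] = 0  # monomorphic column
        y = rng.standard_normal(40)
        p = anova_pvalues(G, y)
        for j in range(12):
            f = oneway_anova_f(y, G[:, j])
            if np.isnan(f):
                assert np.isnan(p[j])
            else:
                expected = parametric_pvalue(f, statistic_spec("oneway_anova", y, G[:, j]))
                assert p[j] == pytest.approx(expected, rel=1e-9)

    def test_null_pvalues_are_uniform(self):
        """Parametric p-values over many simulated null SNPs pass a KS test."""
        r = np.random.default_rng(11)
        G = (r.random((100, 10_000)) < 0.1).astype(np.int8) + (
            r.random((100, 10_000)) < 0.1
        ).astype(np.int8)
        y = r.standard_normal(100)
        p = anova_pvalues(G, y)
        p = p[np.isfinite(p)]
        assert sps.kstest(p, "uniform").pvalue > 0.01
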