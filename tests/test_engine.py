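"""Permutation engines: estimator branches, oracle agreement, concordance."""

import itertools
import math

import numpy as np
import pytest

from adaperm import (
    PermutationPlan,
    adaptive_permute,
    estimate_adaptive_p,
    scan,
    standard_permute,
    success_stream,
)
from adaperm.stats import oneway_anova_f


def exhaustive_permutation_p(y, g):
    """Exact permutation p-value by full enumeration (tiny n only).

    Genuine F ties (permutations assigning the same value multiset to each
    group) count as successes, matching the engine's >= convention; a small
    relative tolerance keeps float noise from splitting those ties.
    """
    f_obs = oneway_anova_f(y, g)
    n_tot = 0
    n_hit = 0
    for perm in itertools.permutations(y):
        n_tot += 1
        f = oneway_anova_f(np.array(perm), g)
        if f >= f_obs or np.isclose(f, f_obs, rtol=1e-9):
            n_hit += 1
    return n_hit / n_tot


class TestEstimator:
    def test_stopped_branch(self):
        assert estimate_adaptive_p(R=115, B=2300, r=115, b=9900) == pytest.approx(0.05)

    def test_censored_branch_zero_successes(self):
        assert estimate_adaptive_p(R=0, B=9900, r=120, b=9900) == pytest.approx(1 / 9901)

    def test_every_permutation_succeeding_gives_one(self):
        assert estimate_adaptive_p(R=20, B=20, r=20, b=100) == 1.0

    def test_inconsistent_states_rejected(self):
        with pytest.raises(ValueError):
            estimate_adaptive_p(R=5, B=50, r=10, b=100)  # censored but B != b
        with pytest.raises(ValueError):
            estimate_adaptive_p(R=10, B=2000, r=10, b=100)  # B beyond budget
        with pytest.raises(ValueError):
            estimate_adaptive_p(R=11, B=50, r=10, b=100)  # R beyond cutoff


class TestAdaptiveEngine:
    def test_null_estimate_tracks_exhaustive_oracle(self, small_plan):
        """On n=7 data the adaptive estimate sits in the precision band
        around the exactly enumerable permutation p-value."""
        r = np.random.default_rng(42)
        inside = 0
        runs = 40
        for k in range(runs):
            g = np.array([0, 0, 0, 1, 1, 2, 2])
            y = r.standard_normal(7)
            p_exact = exhaustive_permutation_p(y, g)
            plan = PermutationPlan(m=1, alpha_e=0.05, alpha_p=0.05, c=0.1, b=9900, r=115)
            res = adaptive_permute(y, g, plan, rng=k)
            if abs(res.p_hat - p_exact) <= 2 * plan.c * p_exact:
                inside += 1
        assert inside >= int(0.85 * runs)

    def test_minimal_observed_statistic_gives_p_one(self, tiny_plan):
        # group means exactly equal -> F_obs = 0, every permutation succeeds
        y = np.tile([1.0, 2.0], 9)
        g = np.repeat([0, 1, 2], 6)
        res = adaptive_permute(y, g, tiny_plan, rng=1)
        assert res.stopped_early
        assert res.B == tiny_plan.r
        assert res.p_hat == 1.0

    def test_huge_effect_exhausts_budget(self, tiny_plan):
        r = np.random.default_rng(0)
        g = r.integers(0, 3, 100)
        y = 10.0 * g + 0.01 * r.standard_normal(100)
        res = adaptive_permute(y, g, tiny_plan, rng=5)
        assert not res.stopped_early
        assert res.B == tiny_plan.b
        assert res.R == 0
        assert res.p_hat == pytest.approx(1 / (tiny_plan.b + 1))

    def test_untestable_flagged_not_raised(self, tiny_plan):
        res = adaptive_permute(np.arange(10.0), np.zeros(10), tiny_plan, rng=0)
        assert res.untestable
        assert np.isnan(res.p_hat)

    def test_deterministic_under_fixed_seed(self, tiny_plan, rng):
        g = rng.integers(0, 3, 50)
        y = rng.standard_normal(50)
        a = adaptive_permute(y, g, tiny_plan, rng=99)
        b = adaptive_permute(y, g, tiny_plan, rng=99)
        assert (a.R, a.B, a.p_hat) == (b.R, b.B, b.p_hat)
        c = adaptive_permute(y, g, tiny_plan, rng=100)
        assert (a.R, a.B) != (c.R, c.B)

    def test_invariants_of_result(self, tiny_plan, rng):
        for seed in range(10):
            g = rng.integers(0, 3, 40)
            y = rng.standard_normal(40)
            res = adaptive_permute(y, g, tiny_plan, rng=seed)
            if res.stopped_early:
                assert res.R == tiny_plan.r
                assert res.p_hat == pytest.approx(tiny_plan.r / res.B)
                assert res.B <= tiny_plan.b
            else:
                assert res.B == tiny_plan.b
                assert res.R < tiny_plan.r
                assert res.p_hat == pytest.approx((res.R + 1) / (tiny_plan.b + 1))
            assert 0 < res.p_hat <= 1


class TestStandardEngine:
    def test_success_count_is_binomial(self):
        """Repeated standard runs on fixed tiny data give R ~ Bin(b, p_exact)."""
        r = np.random.default_rng(3)
        g = np.array([0, 0, 0, 1, 1, 2, 2])
        y = r.standard_normal(7)
        p_exact = exhaustive_permutation_p(y, g)
        b = 400
        counts = np.array(
            [standard_permute(y, g, b, rng=k).R for k in range(150)]
        )
        mean_se = math.sqrt(b * p_exact * (1 - p_exact) / 150)
        assert abs(counts.mean() - b * p_exact) <= 4 * mean_se
        var_expected = b * p_exact * (1 - p_exact)
        assert 0.5 * var_expected <= counts.var(ddof=1) <= 1.7 * var_expected

    def test_perfect_separation_reports_zero(self):
        r = np.random.default_rng(1)
        g = r.integers(0, 3, 60)
        y = g + 0.001 * r.standard_normal(60)
        res = standard_permute(y, g, 300, rng=2)
        assert res.R == 0
        assert res.p_hat == 0.0
        res2 = standard_permute(y, g, 300, rng=2, add_one=True)
        assert res2.p_hat == pytest.approx(1 / 301)

    def test_minimal_statistic_gives_p_one(self):
        y = np.tile([1.0, 2.0], 9)
        g = np.repeat([0, 1, 2], 6)
        res = standard_permute(y, g, 100, rng=0)
        assert res.R == 100
        assert res.p_hat == 1.0


class TestConcordance:
    def test_shared_stream_success_counts_agree(self, tiny_plan, rng):
        """Adaptive and standard engines consume the identical permutation
        stream under one seed: indicators reproduce both outcomes."""
        for seed in range(8):
            g = rng.integers(0, 3, 50)
            y = rng.standard_normal(50)
            stream = success_stream(y, g, tiny_plan.b, rng=seed)
            ares = adaptive_permute(y, g, tiny_plan, rng=seed)
            assert stream[: ares.B].sum() == ares.R
            if ares.stopped_early:
                assert stream[ares.B - 1] == 1  # r-th success exactly at B
            sres = standard_permute(y, g, tiny_plan.b, rng=seed)
            assert stream.sum() == sres.R

    def test_strict_ties_never_exceed_weak_ties(self, rng):
        g = rng.integers(0, 2, 12)
        y = rng.integers(0, 3, 12).astype(float)  # discrete trait forces ties
        weak = success_stream(y, g, 500, rng=7, tie="geq")
        strict = success_stream(y, g, 500, rng=7, tie="gt")
        assert strict.sum() <= weak.sum()
        assert np.all(strict <= weak)


class TestScan:
    def test_null_scan_calls_nothing(self, rng):
        plan = PermutationPlan(m=3, alpha_e=0.05, alpha_p=0.05 / 3, c=0.1, b=1000, r=50)
        G = rng.integers(0, 3, size=(30, 3))
        y = rng.standard_normal(30)
        results = scan(G, y, plan, rng=17)
        assert len(results) == 3
        assert not any(r.significant for r in results)

    def test_strong_snp_called_significant(self):
        r = np.random.default_rng(8)
        plan = PermutationPlan(m=3, alpha_e=0.05, alpha_p=0.05 / 3, c=0.1, b=600, r=50)
        G = r.integers(0, 3, size=(200, 3))
        y = 1.8 * G[:, 1] + r.standard_normal(200)
        results = scan(G, y, plan, rng=3)
        assert results[1].significant
        assert results[1].B == plan.b  # evidence strong enough to exhaust budget
        assert not results[0].significant and not results[2].significant

    def test_empty_matrix(self, tiny_plan, rng):
        assert scan(np.empty((10, 0)), rng.standard_normal(10), tiny_plan) == []

    def test_dimension_mismatch_rejected(self, tiny_plan, rng):
        with pytest.raises(ValueError):
            scan(rng.integers(0, 3, (10, 2)), np.zeros(11), tiny_plan)

    def test_mixed_untestable_columns(self, tiny_plan, rng):
        G = rng.integers(0, 3, size=(40, 3))
        G[:, 2] = 1  # monomorphic
        y = rng.standard_normal(40)
        results = scan(G, y, tiny_plan, rng=4)
        assert results[2].untestable and not results[0].untestable

    def test_order_independent_per_snp_streams(self, tiny_plan, rng):
        """Result of a SNP depends on (seed, column index) only."""
        G = rng.integers(0, 3, size=(50, 4))
        y = rng.standard_normal(50)
        full = scan(G, y, tiny_plan, rng=5)
        again = scan(G, y, tiny_plan, rng=5)
        assert [(r.R, r.B) for r in full] == [(r.R, r.B) for r in again]
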