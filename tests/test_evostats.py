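"""Distribution fitting, two-group LRT, rank tests, bootstraps, UPGMA
clustering with nested comparisons, and correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaboconstraint import evostats
from metaboconstraint.errors import InvalidParameterError


class TestFitDistribution:
    def test_exponential_closed_form_rate(self):
        fit = evostats.fit_distribution([1, 2, 3, 4, 5], "exponential")
        # scale = mean, so the rate 1/scale is 1/3
        assert 1.0 / fit.params[-1] == pytest.approx(1.0 / 3.0)
        assert fit.k == 1

    def test_weibull_parameter_recovery(self):
        rng = np.random.default_rng(0)
        data = 0.15 * rng.weibull(2.0, size=10_000)
        fit = evostats.fit_distribution(data, "weibull")
        shape, _, scale = fit.params
        assert shape == pytest.approx(2.0, rel=0.05)
        assert scale == pytest.approx(0.15, rel=0.05)

    def test_nonpositive_data_rejected_for_positive_families(self):
        with pytest.raises(InvalidParameterError):
            evostats.fit_distribution([-1.0, 0.5, 1.0, 2.0, 3.0], "gamma")

    def test_tiny_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            evostats.fit_distribution([1.0, 2.0, 3.0], "exponential")

    def test_parameter_counts_match_family(self):
        rng = np.random.default_rng(1)
        data = rng.gamma(2.0, 0.1, size=200)
        for family, k in [
            ("weibull", 2),
            ("gamma", 2),
            ("exponential", 1),
            ("logistic", 2),
            ("normal", 2),
            ("extreme_value", 3),
            ("lognormal", 2),
            ("cauchy", 2),
        ]:
            assert evostats.fit_distribution(data, family).k == k


class TestQQRanking:
    def test_perfect_quantiles_give_r_one(self):
        probs = (np.arange(1, 201) - 0.5) / 200
        data = stats.weibull_min.ppf(probs, 2.0, scale=0.15)
        fit = evostats.fit_distribution(data, "weibull")
        assert evostats.qq_pearson_r(data, fit) == pytest.approx(1.0, abs=1e-4)

    def test_constant_data_flagged(self):
        fit = evostats.FitResult("normal", (0.0, 1.0), 0.0, 2)
        with pytest.raises(InvalidParameterError):
            evostats.qq_pearson_r(np.ones(10), fit)

    def test_weibull_data_ranks_weibull_like_families_top(self):
        rng = np.random.default_rng(3)
        wins = 0
        for seed in range(5):
            data = 0.14 * np.random.default_rng(seed).weibull(2.0, size=3000)
            ranking = evostats.rank_distributions(data)
            top3 = set(ranking.family.iloc[:3])
            cauchy_r = float(ranking.loc[ranking.family == "cauchy", "qq_r"].iloc[0])
            weibull_r = float(ranking.loc[ranking.family == "weibull", "qq_r"].iloc[0])
            assert weibull_r > cauchy_r
            wins += {"weibull", "gamma"} <= top3
        assert wins >= 4

    def test_top_family_is_unique(self):
        data = 0.14 * np.random.default_rng(5).weibull(2.0, size=500)
        ranking = evostats.rank_distributions(data)
        best = ranking.iloc[0]
        runners = ranking.iloc[1:]
        assert not (
            (runners.qq_r == best.qq_r) & (runners.loglik == best.loglik)
        ).any()


class TestTwoGroupLRT:
    def test_identical_groups_give_zero_statistic(self):
        data = 0.14 * np.random.default_rng(0).weibull(2.0, size=400)
        t = evostats.two_group_lrt(data, data, "weibull")
        assert t.statistic == pytest.approx(0.0, abs=1e-4)
        assert t.p_value == pytest.approx(1.0, abs=1e-3)
        assert t.df == 2

    def test_statistic_nonnegative_up_to_tolerance(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.gamma(2.0, 0.1, size=150)
            y = rng.gamma(2.0, 0.1, size=250)
            t = evostats.two_group_lrt(x, y, "gamma")
            assert t.statistic >= -1e-6


class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        t = evostats.mann_whitney([1, 2, 3, 4], [5, 6, 7, 8], "less")
        assert t.p_value == pytest.approx(1 / 70)

    def test_three_vs_three_exact_p(self):
        t = evostats.mann_whitney([1, 2, 3], [4, 5, 6], "less")
        assert t.p_value == pytest.approx(1 / 20)

    def test_exact_matches_reference_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            nx_ = int(rng.integers(2, 6))
            ny_ = int(rng.integers(2, 6))
            pool = rng.permutation(np.arange(1.0, 13.0))
            x, y = pool[:nx_], pool[nx_ : nx_ + ny_]
            for alt in ("less", "greater", "two-sided"):
                ours = evostats.mann_whitney(x, y, alt)
                ref = stats.mannwhitneyu(x, y, alternative=alt, method="exact")
                assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.4, 1, 80)
        ours = evostats.mann_whitney(x, y, "two-sided")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-6)


class TestChisq2x2:
    def test_independent_table_is_zero(self):
        assert evostats.chisq_2x2([[10, 10], [10, 10]]).statistic == 0.0

    def test_closed_form_value(self):
        t = evostats.chisq_2x2([[30, 10], [10, 30]])
        assert t.statistic == pytest.approx(20.0)
        assert t.df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(InvalidParameterError):
            evostats.chisq_2x2([[0, 5], [0, 5]])


class TestBootstraps:
    def test_mean_test_centered_at_half_under_null(self):
        rng = np.random.default_rng(4)
        pool = rng.gamma(2.0, 0.1, size=2000)
        t = evostats.bootstrap_mean_test(
            pool, n_sub=200, n_reps=4000, observed_mean=float(pool.mean()),
            tail="less", seed=1,
        )
        assert 0.42 <= t.p_value <= 0.58

    def test_unreachable_observation_attains_lower_bound(self):
        pool = np.linspace(1.0, 2.0, 100)
        t = evostats.bootstrap_mean_test(
            pool, n_sub=10, n_reps=999, observed_mean=0.0, tail="less", seed=2
        )
        assert t.p_value == pytest.approx(1 / 1000)

    def test_seed_reproducibility(self):
        pool = np.random.default_rng(5).gamma(2.0, 0.1, size=500)
        kwargs = dict(n_sub=50, n_reps=500, observed_mean=0.19, tail="less")
        a = evostats.bootstrap_mean_test(pool, seed=9, **kwargs)
        b = evostats.bootstrap_mean_test(pool, seed=9, **kwargs)
        assert a.p_value == b.p_value

    def test_diff_test_zero_observed_is_nonsignificant(self):
        pool = np.random.default_rng(6).gamma(2.0, 0.1, size=1000)
        t = evostats.bootstrap_diff_test(
            pool, n1=100, n2=400, n_reps=500, observed_diff=0.0, seed=3
        )
        assert t.p_value > 0.9

    def test_diff_test_detects_planted_shift(self):
        rng = np.random.default_rng(7)
        a = 0.13 * rng.weibull(2.0, 1190)
        b = 0.15 * rng.weibull(2.0, 5000)
        pool = np.concatenate([a, b])
        t = evostats.bootstrap_diff_test(
            pool, n1=len(a), n2=len(b), n_reps=2000,
            observed_diff=float(a.mean() - b.mean()), seed=4,
        )
        assert t.p_value <= 1e-3

    def test_p_values_within_estimator_bounds(self):
        pool = np.random.default_rng(8).gamma(2.0, 0.1, size=200)
        t = evostats.bootstrap_mean_test(
            pool, 20, 100, observed_mean=float(np.median(pool)), tail="greater",
            seed=5,
        )
        assert 1 / 101 <= t.p_value <= 1.0


class TestUPGMANested:
    def test_nearest_means_merge_first(self):
        rng = np.random.default_rng(9)
        groups = {
            "a": rng.normal(1.0, 0.1, 30),
            "b": rng.normal(2.0, 0.1, 30),
            "c": rng.normal(10.0, 0.1, 30),
        }
        newick, comparisons = evostats.upgma_nested_tests(groups)
        assert set(comparisons[0].left + comparisons[0].right) == {"a", "b"}
        assert "(a,b)" in newick and newick.endswith(";")

    def test_nine_groups_yield_eight_comparisons(self):
        rng = np.random.default_rng(10)
        groups = {
            f"g{k}": rng.normal(k * 0.02 + 0.1, 0.03, 40) for k in range(9)
        }
        _, comparisons = evostats.upgma_nested_tests(groups)
        assert len(comparisons) == 8

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(11)
        base = rng.gamma(2.0, 0.05, 60)
        _, comparisons = evostats.upgma_nested_tests(
            {"a": base, "b": rng.permutation(base)}, alpha=0.01
        )
        assert not comparisons[0].significant

    def test_single_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            evostats.upgma_nested_tests({"a": [1.0, 2.0]})


class TestCorrelate:
    def test_monotone_pair_has_spearman_one(self):
        x = np.arange(1.0, 11.0)
        t = evostats.correlate(x, np.exp(x), "spearman")
        assert t.statistic == pytest.approx(1.0)

    def test_log10_requires_positive_x(self):
        with pytest.raises(InvalidParameterError):
            evostats.correlate([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], x_transform="log10")

    def test_zero_variance_flagged_not_raised(self):
        t = evostats.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(t.statistic) and t.note is not None


class TestMaxExpression:
    def test_single_column_is_identity(self):
        df = pd.DataFrame({"t0": [1.0, 5.0]}, index=["g1", "g2"])
        assert evostats.max_expression(df).tolist() == [1.0, 5.0]

    def test_row_maximum(self):
        df = pd.DataFrame([[1.0, 5.0, 3.0]], index=["g"], columns=list("abc"))
        assert evostats.max_expression(df)["g"] == 5.0

    def test_all_missing_row_dropped_with_warning(self):
        df = pd.DataFrame(
            [[1.0, 2.0], [np.nan, np.nan]], index=["keep", "drop"]
        )
        with pytest.warns(UserWarning):
            out = evostats.max_expression(df)
        assert list(out.index) == ["keep"]
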