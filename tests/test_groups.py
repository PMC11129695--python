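import itertools
import math

import numpy as np
import pytest

from luregait import (
    DisplaySummary,
    bootstrap_and_fit,
    bootstrap_movements,
    compare_groups,
    fit_interval_mixed_model,
    rank_sum_test,
    temperature_correlation,
)


def summary(rid, mean_interval=1.0, sd=0.2, duration=0.4, prop=0.5, temp=None):
    return DisplaySummary(
        recording_id=rid,
        mean_interval_left=mean_interval, mean_interval_right=mean_interval,
        sd_interval_left=sd, sd_interval_right=sd,
        mean_duration_left=duration, mean_duration_right=duration,
        n_movements_left=10, n_movements_right=10,
        proportion_sync=prop, water_temp=temp,
    )


def ranksum_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(x) + sorted(y)
    n1 = len(x)

    def u_stat(first):
        # U = number of (a, b) pairs with a from the first sample and a > b
        rest = list(pooled)
        for v in first:
            rest.remove(v)
        return sum(a > b for a in first for b in rest)

    u_obs = u_stat(list(x))
    us = [u_stat(list(c)) for c in itertools.combinations(pooled, n1)]
    total = len(us)
    p_low = sum(u <= u_obs for u in us) / total
    p_high = sum(u >= u_obs for u in us) / total
    return min(1.0, 2 * min(p_low, p_high))


class TestRankSum:
    def test_complete_separation_gives_w_zero(self):
        w, p = rank_sum_test([1, 2, 3], [10, 20, 30])
        assert w == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 assignments

    @pytest.mark.parametrize("x, y", [
        ([1, 2, 3], [4, 5, 6]),
        ([1, 5, 9], [2, 3, 12]),
        ([0.1, 0.2, 0.7, 0.9], [0.3, 0.5]),
        ([3, 8, 11, 15, 20], [1, 2, 9, 10]),
    ])
    def test_exact_p_matches_enumeration(self, x, y):
        _, p = rank_sum_test(x, y)
        assert p == pytest.approx(ranksum_enumeration(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=5)
        w1, p1 = rank_sum_test(x, y)
        w2, p2 = rank_sum_test(np.exp(x), np.exp(y))
        assert (w1, p1) == (w2, p2)


class TestCompareGroups:
    def grouping(self, summaries):
        return {s.recording_id: s.recording_id.split("_")[0] for s in summaries}

    def test_identical_groups_no_signal(self):
        summaries = [summary(f"{g}_{i}") for g in "abc" for i in range(3)]
        res = compare_groups(summaries, self.grouping(summaries), "mean_interval")
        assert res.h_statistic == 0.0
        assert all(t.p_adjusted == 1.0 for t in res.pairwise)

    def test_separated_groups_flagged(self):
        summaries = (
            [summary(f"a_{i}", mean_interval=0.2 + 0.01 * i) for i in range(4)]
            + [summary(f"b_{i}", mean_interval=3.0 + 0.1 * i) for i in range(5)]
        )
        res = compare_groups(summaries, self.grouping(summaries), "mean_interval")
        (test,) = res.pairwise
        assert test.statistic == 0.0
        assert test.p_adjusted < 0.05

    def test_bonferroni_multiplier_is_pair_count(self):
        summaries = [summary(f"{g}_{i}", mean_interval=float(ord(g)) + i * 0.1)
                     for g in "abc" for i in range(3)]
        res = compare_groups(summaries, self.grouping(summaries), "mean_interval")
        assert len(res.pairwise) == 3
        for t in res.pairwise:
            assert t.p_adjusted == pytest.approx(min(1.0, t.p_raw * 3))
            assert t.p_adjusted >= t.p_raw

    def test_metric_absent_for_group_raises(self):
        summaries = [summary("a_0"), summary("a_1"),
                     DisplaySummary(
                         recording_id="b_0",
                         mean_interval_left=None, mean_interval_right=None,
                         sd_interval_left=None, sd_interval_right=None,
                         mean_duration_left=None, mean_duration_right=None,
                         n_movements_left=0, n_movements_right=0,
                         proportion_sync=None)]
        with pytest.raises(ValueError, match="'b'"):
            compare_groups(summaries, self.grouping(summaries), "mean_interval")

    def test_single_group_raises(self):
        summaries = [summary("a_0"), summary("a_1")]
        with pytest.raises(ValueError, match="2 groups"):
            compare_groups(summaries, self.grouping(summaries), "mean_interval")


class TestTemperatureCorrelation:
    def test_monotone_cases(self):
        inc = [summary(f"r{i}", mean_interval=i + 1.0, temp=10.0 + i)
               for i in range(5)]
        rho, _ = temperature_correlation(inc)
        assert rho == pytest.approx(1.0)
        dec = [summary(f"r{i}", mean_interval=5.0 - i, temp=10.0 + i)
               for i in range(5)]
        rho, _ = temperature_correlation(dec)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula_n4(self):
        temps = [10.0, 12.0, 14.0, 16.0]
        intervals = [1.4, 1.1, 1.9, 1.2]
        summaries = [summary(f"r{i}", mean_interval=iv, temp=t)
                     for i, (t, iv) in enumerate(zip(temps, intervals))]
        rho, _ = temperature_correlation(summaries)
        rt = [sorted(temps).index(t) + 1 for t in temps]
        ri = [sorted(intervals).index(v) + 1 for v in intervals]
        d2 = sum((a - b) ** 2 for a, b in zip(rt, ri))
        n = 4
        assert rho == pytest.approx(1 - 6 * d2 / (n * (n**2 - 1)))

    def test_too_few_points_raises(self):
        summaries = [summary("r0", temp=10.0), summary("r1", temp=11.0)]
        with pytest.raises(ValueError):
            temperature_correlation(summaries)


class TestBootstrap:
    def test_degenerate_single_value(self):
        out = bootstrap_movements(np.array([2.5]), n_boot=50, seed=1)
        assert out.shape == (50,)
        assert (out == 2.5).all()

    def test_default_length_is_1000(self):
        out = bootstrap_movements(np.array([1.0, 2.0]), seed=3)
        assert out.shape == (1000,)

    def test_mean_converges(self):
        values = np.array([1.0, 2.0, 3.0])
        out = bootstrap_movements(values, n_boot=20000, seed=7)
        se = values.std() / math.sqrt(out.size)
        assert abs(out.mean() - 2.0) < 3 * se

    def test_seed_reproducibility(self):
        a = bootstrap_movements(np.arange(5.0), n_boot=100, seed=11)
        b = bootstrap_movements(np.arange(5.0), n_boot=100, seed=11)
        assert (a == b).all()

    def test_empty_values_raise(self):
        with pytest.raises(ValueError):
            bootstrap_movements(np.array([]), seed=0)


class TestMixedModel:
    def grouping(self, boot):
        return {rid: rid.split("_")[0] for rid in boot}

    def test_identical_groups_zero_contrast(self):
        vals = np.array([1.0, 1.2, 0.9, 1.1])
        boot = {f"{g}_{i}": vals for g in "ab" for i in range(3)}
        res = fit_interval_mixed_model(boot, self.grouping(boot), seed=0)
        (contrast,) = res.contrasts
        assert contrast.estimate == pytest.approx(0.0, abs=1e-8)
        assert res.group_means["a"] == pytest.approx(res.group_means["b"])

    def test_parameter_recovery_two_groups(self, rng):
        """Group means 0.2 s and 3.2 s with small between-recording spread are
        recovered inside the estimate ± 2 SE interval."""
        interval_sets = {}
        for g, mu in (("a", 0.2), ("b", 3.2)):
            for i in range(6):
                centre = mu + rng.normal(0, 0.05)
                interval_sets[f"{g}_{i}"] = np.maximum(
                    rng.normal(centre, 0.1, size=40), 0.01)
        res = bootstrap_and_fit(interval_sets, self.grouping(interval_sets),
                                n_boot=300, seed=5)
        (contrast,) = res.contrasts
        assert abs(contrast.estimate - 3.0) < 2 * contrast.se + 0.1
        assert res.group_means["a"] == pytest.approx(0.2, abs=0.15)
        assert res.group_means["b"] == pytest.approx(3.2, abs=0.15)
        assert contrast.df > 0

    def test_satterthwaite_df_near_between_recording_df(self, rng):
        """With many bootstrap draws per recording the contrast df approaches
        recordings − groups: the replication unit is the individual."""
        interval_sets = {
            f"{g}_{i}": np.maximum(rng.normal(mu + rng.normal(0, 0.3), 0.2, 30),
                                   0.01)
            for g, mu in (("a", 1.0), ("b", 2.0)) for i in range(8)
        }
        res = bootstrap_and_fit(interval_sets, self.grouping(interval_sets),
                                n_boot=400, seed=9)
        (contrast,) = res.contrasts
        assert 0.5 * 14 < contrast.df < 1.5 * 14

    def test_bootstrap_inflation_barely_moves_se(self, rng):
        """Random intercepts keep inference driven by between-recording
        variation: 10x more bootstrap draws changes contrast SE < 10%."""
        interval_sets = {
            f"{g}_{i}": np.maximum(rng.normal(mu + rng.normal(0, 0.3), 0.2, 30),
                                   0.01)
            for g, mu in (("a", 1.0), ("b", 2.0)) for i in range(6)
        }
        grouping = self.grouping(interval_sets)
        se_small = bootstrap_and_fit(interval_sets, grouping, n_boot=100,
                                     seed=2).contrasts[0].se
        se_large = bootstrap_and_fit(interval_sets, grouping, n_boot=1000,
                                     seed=2).contrasts[0].se
        assert abs(se_large - se_small) / se_small < 0.10

    def test_seed_reproducibility(self, rng):
        interval_sets = {
            f"{g}_{i}": np.abs(rng.normal(1.5, 0.4, 20))
            for g in "ab" for i in range(4)
        }
        grouping = self.grouping(interval_sets)
        r1 = bootstrap_and_fit(interval_sets, grouping, n_boot=100, seed=42)
        r2 = bootstrap_and_fit(interval_sets, grouping, n_boot=100, seed=42)
        assert r1.group_means == r2.group_means
        assert r1.contrasts[0].p == r2.contrasts[0].p

    def test_single_group_raises(self):
        boot = {"a_0": np.ones(10), "a_1": np.ones(10)}
        with pytest.raises(ValueError):
            fit_interval_mixed_model(boot, self.grouping(boot), seed=0)
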