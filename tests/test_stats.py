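"""Statistical battery: oracles, invariants and calibration."""
import numpy as np
import pandas as pd
import pytest

from microquant import stats


class TestOutliers:
    def test_single_extreme_point_survives_small_sample(self):
        # {0,0,0,0,100}: mean 20, SD ~44.7 — no point beyond 3 SD
        res = stats.remove_outliers([0, 0, 0, 0, 100])
        assert res.removed_indices.size == 0
        assert res.kept.size == 5

    def test_constructed_outlier_removed(self):
        # 30 values near 10 plus one injected at 4 SD of the full set
        # (fixed point of the filter's own definition)
        base = np.full(30, 10.0)
        base[:5] += [0.5, -0.5, 0.25, -0.25, 0.1]
        x = np.append(base, 10.0)
        for _ in range(200):
            x[-1] = x.mean() + 4.0 * x.std(ddof=1)
        assert x[-1] - x.mean() > 3.9 * x.std(ddof=1)  # converged
        res = stats.remove_outliers(x)
        assert list(res.removed_indices) == [len(x) - 1]

    def test_matches_exhaustive_criterion(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 200)
        x[:3] = [8, -9, 7.5]
        res = stats.remove_outliers(x)
        mean, sd = x.mean(), x.std(ddof=1)
        brute = np.flatnonzero(np.abs(x - mean) > 3 * sd)
        np.testing.assert_array_equal(res.removed_indices, brute)

    def test_all_equal_unchanged(self):
        res = stats.remove_outliers([4.0] * 10)
        assert res.removed_indices.size == 0

    def test_small_sample_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            res = stats.remove_outliers([1.0, 2.0])
        assert res.kept.size == 2


class TestNormalizeToControl:
    def test_fold_arithmetic(self):
        table = pd.DataFrame(
            {"condition": ["c"] * 3 + ["t"] * 2, "y": [2.0, 2.0, 2.0, 4.0, 4.0]}
        )
        out = stats.normalize_to_control(table, "y", "c")
        assert list(out.loc[out.condition == "t", "y_fold"]) == [2.0, 2.0]

    def test_control_mean_is_one(self):
        table = pd.DataFrame(
            {
                "condition": ["c", "c", "t", "t"] * 2,
                "replicate": [1, 1, 1, 1, 2, 2, 2, 2],
                "y": [1.0, 3.0, 5.0, 5.0, 10.0, 30.0, 50.0, 50.0],
            }
        )
        out = stats.normalize_to_control(table, "y", "c", replicate_col="replicate")
        assert out.loc[out.condition == "c", "y_fold"].mean() == pytest.approx(1.0)

    def test_missing_control_in_replicate_named(self):
        table = pd.DataFrame(
            {"condition": ["c", "t", "t"], "replicate": [1, 1, 2], "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match=r"\[2\]"):
            stats.normalize_to_control(table, "y", "c", replicate_col="replicate")

    def test_zero_control_mean_named(self):
        table = pd.DataFrame({"condition": ["c", "t"], "y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="zero mean"):
            stats.normalize_to_control(table, "y", "c")


class TestPairedT:
    def test_identical_samples(self):
        res = stats.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_textbook_differences(self):
        # differences {1,2,3}: t = 2*sqrt(3), df 2, p ~ 0.0742
        res = stats.paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0742, abs=5e-4)
        lo, hi = res.ci95
        assert lo < 2.0 < hi  # CI of the mean difference contains it

    def test_antisymmetric_differences(self):
        res = stats.paired_t_test([1.0, 3.0], [2.0, 2.0])
        assert res.statistic == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            stats.paired_t_test([1.0, 2.0], [1.0])


class TestNestedT:
    @staticmethod
    def _table(group_means, droplets_per_patient=1, noise=None):
        rows = []
        for g, means in group_means.items():
            for i, m in enumerate(means):
                for d in range(droplets_per_patient):
                    val = m if noise is None else m + noise[(g, i, d)]
                    rows.append(
                        {"condition": g, "patient_id": f"{g}{i}", "y": val}
                    )
        return pd.DataFrame(rows)

    def test_identical_patient_means(self):
        t = self._table({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        res = stats.nested_t_test(t, "y", "condition")
        assert res.p_value == 1.0

    def test_textbook_patient_means(self):
        # patient means {1,2,3} vs {4,5,6}: pooled t = -3.674, df 4, p ~ 0.0213
        t = self._table({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        res = stats.nested_t_test(t, "y", "condition")
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.p_value == pytest.approx(0.0213, abs=5e-4)
        assert res.n == (3, 3)

    def test_patient_is_the_experimental_unit(self):
        # 1000 droplets per patient but 2 patients/group: df stays 2
        t = self._table({"a": [1.0, 2.0], "b": [4.0, 5.0]}, droplets_per_patient=1000)
        res = stats.nested_t_test(t, "y", "condition")
        assert res.df == 2
        assert res.n == (2, 2)

    def test_pseudo_replication_immunity(self):
        rng = np.random.default_rng(11)
        base = self._table(
            {"a": [1.0, 1.5, 0.7], "b": [2.0, 2.2, 1.9]}, droplets_per_patient=5,
            noise={
                (g, i, d): rng.normal(0, 0.3)
                for g in "ab" for i in range(3) for d in range(5)
            },
        )
        doubled = pd.concat([base, base], ignore_index=True)
        p1 = stats.nested_t_test(base, "y", "condition").p_value
        p2 = stats.nested_t_test(doubled, "y", "condition").p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_patient_in_both_groups_rejected(self):
        t = pd.DataFrame(
            {"condition": ["a", "b"], "patient_id": ["p1", "p1"], "y": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="both groups"):
            stats.nested_t_test(t, "y", "condition")


class TestAnovaTukey:
    def test_identical_groups_null(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        anova, pairs = stats.anova_tukey(g)
        assert anova.statistic == pytest.approx(0.0, abs=1e-12)
        assert all(p.p_value > 0.999 for p in pairs)

    def test_matches_statsmodels_reference(self):
        # independent reference route: statsmodels pairwise_tukeyhsd
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        from scipy.stats import f_oneway

        g = {"g1": [1.0, 2.0, 3.0], "g2": [2.0, 3.0, 4.0], "g3": [7.0, 8.0, 9.0]}
        anova, pairs = stats.anova_tukey(g)
        f_ref, p_ref = f_oneway(*g.values())
        assert anova.statistic == pytest.approx(f_ref, abs=1e-10)
        assert anova.p_value == pytest.approx(p_ref, abs=1e-10)

        data = np.concatenate(list(g.values()))
        labels = np.repeat(list(g), [len(v) for v in g.values()])
        ref = pairwise_tukeyhsd(data, labels)
        ref_p = {
            (str(r[0]), str(r[1])): float(r[3]) for r in ref.summary().data[1:]
        }
        for pair in pairs:
            key = (pair.groups[0], pair.groups[1])
            assert pair.p_value == pytest.approx(ref_p[key], abs=1e-4)

    def test_tukey_never_below_unadjusted(self):
        rng = np.random.default_rng(2)
        g = {k: rng.normal(i * 0.5, 1, 8) for i, k in enumerate("abcd")}
        _, pairs = stats.anova_tukey(g)
        for pair in pairs:
            raw = stats.two_sample_t_test(g[pair.groups[0]], g[pair.groups[1]])
            assert pair.p_value >= raw.p_value - 1e-12

    def test_two_groups_degrade_with_warning(self):
        with pytest.warns(UserWarning, match="2 groups"):
            res, pairs = stats.anova_tukey({"a": [1.0, 2.0], "b": [2.0, 3.0]})
        assert res.test_name == "student_t" and len(pairs) == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stats.anova_tukey({"a": [1.0, 2.0], "b": [], "c": [1.0, 2.0]})


class TestMeanCI:
    def test_constant_data_zero_width(self):
        mean, lo, hi = stats.mean_ci95([5.0, 5.0, 5.0])
        assert (mean, lo, hi) == (5.0, 5.0, 5.0)

    def test_textbook_interval(self):
        mean, lo, hi = stats.mean_ci95([1, 2, 3, 4, 5])
        assert mean == 3.0
        assert lo == pytest.approx(1.036, abs=1e-3)
        assert hi == pytest.approx(4.964, abs=1e-3)

    def test_width_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 100)
        _, lo1, hi1 = stats.mean_ci95(x)
        y = np.tile(x, 4)  # same SD, 4x n
        _, lo2, hi2 = stats.mean_ci95(y)
        assert (hi2 - lo2) == pytest.approx((hi1 - lo1) / 2, rel=0.05)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            stats.mean_ci95([1.0])


class TestStars:
    @pytest.mark.parametrize(
        "p,code",
        [
            (0.04, "*"),
            (0.05, "ns"),
            (0.5, "ns"),
            (0.009, "**"),
            (0.01, "*"),
            (0.0009, "***"),
            (5e-5, "****"),
            (1e-4, "***"),
        ],
    )
    def test_mapping(self, p, code):
        assert stats.star_code(p) == code

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.star_code(1.5)


class TestStatsResult:
    def test_invalid_ci_rejected(self):
        with pytest.raises(ValueError, match="ci95"):
            stats.StatsResult("t", ("a", "b"), (2, 2), 0.0, 1.0, 0.5, ci95=(1.0, 0.0))

    def test_serializable(self):
        import json

        res = stats.paired_t_test([1.0, 2.0, 4.0], [0.0, 1.0, 2.0])
        json.dumps(res.to_dict())


class TestCalibration:
    """All CIs contain their sample mean; p-values stay in [0, 1]."""

    def test_ci_contains_mean_and_p_in_range(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0, 1, 8)
            res = stats.paired_t_test(x, y)
            assert 0.0 <= res.p_value <= 1.0
            lo, hi = res.ci95
            assert lo <= np.mean(x - y) <= hi
            mean, lo, hi = stats.mean_ci95(x)
            assert lo <= mean <= hi
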