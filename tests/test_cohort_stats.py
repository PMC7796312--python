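import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from colorfaf import cohort_stats as cs
from colorfaf.imaging_io import cohort_from_records
from colorfaf.synthetic_data import CohortSimConfig, generate_cohort

finite_samples = st.lists(
    st.floats(-1e3, 1e3, allow_nan=False), min_size=2, max_size=30
)


class TestTTest:
    def test_dm_vs_control_printed_summaries(self):
        """Published foveal DM-vs-control comparisons re-derive from mean/SD/n."""
        res = cs.ttest_from_summary(
            cs.GroupSummary(17.4, 14.1, 152), cs.GroupSummary(9.1, 6.1, 18)
        )
        assert res.df == 168
        assert round(res.p, 3) == 0.015
        res = cs.ttest_from_summary(
            cs.GroupSummary(18.5, 12.6, 152), cs.GroupSummary(10.0, 6.6, 18)
        )
        assert round(res.p, 3) == 0.006

    def test_identical_summaries_null(self):
        g = cs.GroupSummary(5.0, 2.0, 10)
        res = cs.ttest_from_summary(g, g)
        assert (res.t, res.p) == (0.0, 1.0)

    def test_identical_raw_samples_null(self):
        res = cs.ttest_raw([1, 2, 3], [1, 2, 3])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_zero_variance_distinct_means_flagged(self):
        res = cs.ttest_raw([0.0, 0.0], [1.0, 1.0])
        assert res.degenerate
        assert math.isnan(res.p)

    def test_welch_differs_with_unequal_variances(self):
        a, b = cs.GroupSummary(10.0, 1.0, 50), cs.GroupSummary(11.0, 8.0, 8)
        pooled = cs.ttest_from_summary(a, b, "pooled")
        welch = cs.ttest_from_summary(a, b, "welch")
        assert pooled.p != welch.p
        assert welch.df < pooled.df

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            cs.ttest_raw([1.0], [1.0, 2.0])

    @given(finite_samples, finite_samples)
    def test_raw_equals_summary_form(self, x, y):
        """Raw and summary-statistic pooled t-tests agree to 1e-12."""
        raw = cs.ttest_raw(x, y)
        summ = cs.ttest_from_summary(
            cs.GroupSummary.from_sample(x), cs.GroupSummary.from_sample(y)
        )
        if raw.degenerate:
            assert summ.degenerate
            return
        assert raw.t == pytest.approx(summ.t, abs=1e-12)
        assert raw.p == pytest.approx(summ.p, abs=1e-12)
        assert raw.df == summ.df


def anova_sums_of_squares_oracle(groups):
    """Direct from-scratch one-way ANOVA and Scheffé p, by sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    k = len(groups)
    n = len(all_vals)
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    f = (ss_between / df_b) / (ss_within / df_w)
    p = sps.f.sf(f, df_b, df_w)
    msw = ss_within / df_w
    scheffe = {}
    for i in range(k):
        for j in range(i + 1, k):
            fij = (np.mean(groups[i]) - np.mean(groups[j])) ** 2 / (
                df_b * msw * (1 / len(groups[i]) + 1 / len(groups[j]))
            )
            scheffe[(i, j)] = sps.f.sf(fij, df_b, df_w)
    return f, p, scheffe


class TestAnovaScheffe:
    def test_identical_groups_null(self):
        res = cs.anova_scheffe([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert (res.f, res.p) == (0.0, 1.0)
        assert (res.scheffe_p == 1.0).all()

    def test_toy_groups_match_sums_of_squares_oracle(self):
        groups = [[1, 2, 3], [2, 3, 4], [9, 10, 11]]
        res = cs.anova_scheffe(groups)
        f, p, scheffe = anova_sums_of_squares_oracle([np.asarray(g, float) for g in groups])
        assert res.f == pytest.approx(f, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        for (i, j), pij in scheffe.items():
            assert res.scheffe_p[i, j] == pytest.approx(pij, abs=1e-10)
        assert res.ls_means == (2.0, 3.0, 10.0)
        assert res.df_between == 2 and res.df_within == 6

    def test_two_groups_scheffe_equals_pooled_t(self, rng):
        """With k=2, F = t² makes the Scheffé p equal the pooled t-test p."""
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1.5, 9)
        res = cs.anova_scheffe([x, y])
        t = cs.ttest_raw(x, y)
        assert res.f == pytest.approx(t.t**2, abs=1e-10)
        assert res.scheffe_p[0, 1] == pytest.approx(t.p, abs=1e-10)
        assert res.p == pytest.approx(t.p, abs=1e-10)

    def test_scheffe_conservative_vs_unadjusted(self, rng):
        """Scheffé pairwise p never falls below the unadjusted contrast p."""
        for _ in range(20):
            k = rng.integers(3, 6)
            groups = [rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(3, 12)) for _ in range(k)]
            res = cs.anova_scheffe(groups)
            n = sum(len(g) for g in groups)
            msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n - k)
            for i in range(k):
                for j in range(i + 1, k):
                    t2 = (groups[i].mean() - groups[j].mean()) ** 2 / (
                        msw * (1 / len(groups[i]) + 1 / len(groups[j]))
                    )
                    p_unadj = sps.f.sf(t2, 1, n - k)
                    assert res.scheffe_p[i, j] >= p_unadj - 1e-12

    def test_matches_statsmodels_anova(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        groups = [rng.normal(m, 1.2, n) for m, n in ((0, 9), (0.5, 14), (1.2, 7))]
        res = cs.anova_scheffe(groups)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat([f"g{i}" for i in range(3)], [len(g) for g in groups]),
            }
        )
        table = sm.stats.anova_lm(ols("y ~ C(g)", data=df).fit(), typ=1)
        assert res.f == pytest.approx(table["F"].iloc[0], rel=1e-9)
        assert res.p == pytest.approx(table["PR(>F)"].iloc[0], rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            cs.anova_scheffe([[1.0], [1.0, 2.0]])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert cs.pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert cs.pearson(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]
        # product-moment by hand: cov = 2.5/3... r = 0.8
        xc = np.asarray(x) - np.mean(x)
        yc = np.asarray(y) - np.mean(y)
        r_hand = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        assert r_hand == pytest.approx(0.8)
        assert cs.pearson(x, y).r == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cs.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=20),
        st.floats(0.1, 10),
        st.floats(-50, 50),
    )
    def test_affine_invariance(self, x, scale, shift):
        y = [((i * 37) % 11) - v for i, v in enumerate(x)]
        if np.std(x) == 0 or np.std(y) == 0:
            return
        r0 = cs.pearson(x, y).r
        r1 = cs.pearson([scale * v + shift for v in x], y).r
        assert r0 == pytest.approx(r1, abs=1e-9)


class TestCompareGroupsTable:
    def test_dme_table_layout_and_power(self):
        """Default synthetic cohorts show the foveal DME separation at p<0.001."""
        n_sig = 0
        reps = 25
        for i in range(reps):
            cohort = generate_cohort(CohortSimConfig(), seed=9000 + i)
            table = cs.compare_groups_table(cohort, grouping="dme")
            assert set(table.columns) == {
                "sector", "component", "mean0", "sd0", "n0",
                "mean1", "sd1", "n1", "t", "df", "p",
            }
            assert len(table) == 18  # 9 sectors x 2 components
            fovea = table[table.sector == "fovea"]
            assert (fovea.n0 == 152).all() and (fovea.n1 == 41).all()
            if (fovea.p < 0.001).all():
                n_sig += 1
        assert n_sig >= 0.95 * reps

    def test_single_class_grouping_skips_all(self):
        cohort = generate_cohort(CohortSimConfig(), seed=5)
        cohort["dme"] = 0
        table = cs.compare_groups_table(cohort, grouping="dme")
        assert table.empty

    def test_small_stratum_rejected(self):
        from test_imaging_io import toy_records

        cohort = cohort_from_records(toy_records())  # one DME eye only
        table = cs.compare_groups_table(cohort, grouping="dme")
        assert table.empty  # n=1 strata are skipped, never tested

    def test_irf_grouping_uses_sector_flags(self):
        cohort = generate_cohort(CohortSimConfig(), seed=11)
        table = cs.compare_groups_table(cohort, grouping="irf")
        fovea = table[table.sector == "fovea"]
        dia = cohort[cohort.group != "control"]
        assert (fovea.n1 == int(dia.irf_fovea.sum())).all()
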