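"""Statistical battery: correctness against closed forms, exact enumeration
oracles, independent library implementations, and type-I calibration."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from ctnps import (
    bonferroni_pairwise,
    levene_test,
    lilliefors_ks,
    oneway_anova,
    oneway_anova_from_summary,
    paired_t,
    partial_eta_sq,
    rm_anova_gg,
    summarize_ordinal,
    wilcoxon_signed_rank,
)
from ctnps.tables import TABLE_HU


class TestLillieforsKS:
    def test_normal_sample_not_rejected(self):
        """Draws from the null distribution should rarely fall below the
        screening threshold p >= 0.01."""
        hits = 0
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(1000)
            _, p = lilliefors_ks(x, n_reps=2000, seed=seed)
            hits += p > 0.1
        assert hits >= 8

    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(42)
        x = np.sort(rng.uniform(0, 1, 200))
        _, p = lilliefors_ks(x, n_reps=2000, seed=0)
        assert p < 0.01

    def test_statistic_matches_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors

        x = np.random.default_rng(7).standard_normal(60)
        d_ours, _ = lilliefors_ks(x, n_reps=500, seed=0)
        d_sm, _ = lilliefors(x, dist="norm")
        assert d_ours == pytest.approx(d_sm, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            lilliefors_ks(np.full(20, 3.0))
        with pytest.raises(ValueError):
            lilliefors_ks([1.0, 2.0, 3.0])


class TestLevene:
    def test_identical_groups(self):
        g = np.arange(10.0)
        w, p = levene_test([g, g.copy()])
        assert w == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_unequal_variances_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 5, 50)
        _, p = levene_test([a, b])
        assert p < 0.01

    def test_type_one_error_calibration(self):
        """Rejection rate under equal variances stays near alpha = 0.05."""
        rng = np.random.default_rng(3)
        rejections = sum(
            levene_test([rng.normal(0, 1, 25), rng.normal(0, 1, 25)])[1] < 0.05
            for _ in range(2000)
        )
        rate = rejections / 2000
        # binomial 99.9% band around 0.05 for 2000 sims
        assert abs(rate - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / 2000)


class TestOnewayAnova:
    def test_identical_groups_give_zero_f(self):
        g = np.arange(12.0)
        f, df1, df2, p = oneway_anova([g, g.copy(), g.copy()])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert (df1, df2) == (2, 33)
        assert p == pytest.approx(1.0)

    def test_two_groups_equal_squared_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 18)
        f, _, _, p_f = oneway_anova([a, b])
        t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t.statistic**2, rel=1e-10)
        assert p_f == pytest.approx(t.pvalue, rel=1e-10)

    def test_gm_summary_anova_significant_at_every_dose(self):
        """Groups rebuilt from the printed GM summaries give p near 0.001;
        WM groups are clearly non-significant - the published pattern."""
        for dose in (1.0, 0.9, 0.7):
            for tissue, expect_sig in (("GM", True), ("WM", False)):
                means, sds = zip(*(TABLE_HU[(tissue, m, dose)] for m in ("FBP", "SAFIRE", "ADMIRE")))
                _, _, _, p = oneway_anova_from_summary(means, sds, [21] * 3)
                assert (p < 0.05) == expect_sig

    def test_summary_and_raw_agree_on_matched_data(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 1, 21) for m in (0.0, 0.3, 0.6)]
        f_raw, *_, p_raw = oneway_anova(groups)
        f_sum, *_, p_sum = oneway_anova_from_summary(
            [g.mean() for g in groups], [g.std(ddof=1) for g in groups], [21] * 3
        )
        assert f_sum == pytest.approx(f_raw, rel=1e-10)
        assert p_sum == pytest.approx(p_raw, rel=1e-10)


class TestBonferroniPairwise:
    def test_mean_differences_from_printed_gm_summaries(self):
        """With groups whose sample means equal the printed Table values,
        the pairwise differences reproduce the published contrasts."""
        rng = np.random.default_rng(0)

        def exact_group(mean, sd, n=21):
            x = rng.standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        groups = {
            m: exact_group(*TABLE_HU[("GM", m, 1.0)]) for m in ("FBP", "SAFIRE", "ADMIRE")
        }
        diffs = {
            (c.group_1, c.group_2): c.mean_difference for c in bonferroni_pairwise(groups)
        }
        assert diffs[("FBP", "SAFIRE")] == pytest.approx(-1.338, abs=5e-4)
        assert diffs[("FBP", "ADMIRE")] == pytest.approx(-0.051, abs=5e-4)
        assert diffs[("SAFIRE", "ADMIRE")] == pytest.approx(1.287, abs=5e-4)

    def test_antisymmetry_and_ci_bracketing(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(i, 1, 10) for i, k in enumerate("abc")}
        comps = {(c.group_1, c.group_2): c for c in bonferroni_pairwise(groups)}
        for (g1, g2), c in comps.items():
            assert c.mean_difference == pytest.approx(-comps[(g2, g1)].mean_difference)
            assert c.ci_low <= c.mean_difference <= c.ci_high

    def test_identical_groups(self):
        g = np.arange(8.0)
        for c in bonferroni_pairwise({"a": g, "b": g.copy()}):
            assert c.mean_difference == 0.0
            assert c.adjusted_p == pytest.approx(1.0)

    def test_adjusted_p_never_below_unadjusted(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            groups = {k: rng.normal(0, 1, 8) for k in "abc"}
            comps = bonferroni_pairwise(groups)
            n_total = 24
            df_w = n_total - 3
            ms_w = sum((g.size - 1) * g.var(ddof=1) for g in groups.values()) / df_w
            for c in comps:
                t = c.mean_difference / c.sem if c.sem else 0.0
                p_un = 2 * sps.t.sf(abs(t), df_w)
                assert c.adjusted_p >= p_un - 1e-12


class TestPairedT:
    def test_identical_pairs(self):
        a = np.arange(10.0)
        t, df, p = paired_t(a, a.copy())
        assert t == pytest.approx(0.0) and df == 9
        assert np.isnan(p) or p == pytest.approx(1.0)

    def test_constant_shift_with_tiny_noise(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 30)
        _, _, p = paired_t(a + 1.0 + rng.normal(0, 1e-6, 30), a)
        assert p < 1e-10

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(2000):
            base = rng.normal(0, 1, 15)
            rejections += paired_t(base + rng.normal(0, 1, 15), base + rng.normal(0, 1, 15))[2] < 0.05
        rate = rejections / 2000
        assert abs(rate - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / 2000)


def _wilcoxon_exact_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumeration of all sign patterns,
    with midranks for tied absolute differences (oracle for n <= 12)."""
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    dev_obs = abs(w_obs - mean_w)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= dev_obs - 1e-9:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        a = np.arange(10.0)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(a, a.copy())

    def test_printed_detail_cell_comparison_significant(self):
        """Score multisets with 10 concordant unit improvements out of 21
        pairs: W = 55 over n = 10 informative pairs, p ~ 0.002."""
        orig = np.array([9] * 20 + [8])
        ninety = np.array([9] * 10 + [8] * 11)
        w, z, p = wilcoxon_signed_rank(orig, ninety)
        assert w == 55.0
        assert z == pytest.approx(3.1623, abs=1e-3)
        assert p < 0.01

    def test_matches_exact_enumeration_for_small_n(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(8, 13)
            a = rng.integers(1, 11, n).astype(float)
            b = rng.integers(1, 11, n).astype(float)
            if np.count_nonzero(a - b) < 5:
                continue
            _, _, p_approx = wilcoxon_signed_rank(a, b)
            p_exact = _wilcoxon_exact_p(a - b)
            # the tie-corrected normal approximation tracks the enumerated p
            assert p_approx == pytest.approx(p_exact, abs=0.1)
            if p_exact < 0.01:
                assert p_approx < 0.05

    def test_matches_scipy_approximation(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 40)
        b = a + rng.normal(0.2, 0.5, 40)
        _, _, p = wilcoxon_signed_rank(a, b)
        res = sps.wilcoxon(a, b, zero_method="wilcox", correction=False, method="approx")
        assert p == pytest.approx(res.pvalue, rel=1e-6)

    def test_shift_invariance(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.3, 1, 25)
        p0 = wilcoxon_signed_rank(a, b)[2]
        p1 = wilcoxon_signed_rank(a + 100.0, b + 100.0)[2]
        assert p0 == pytest.approx(p1, rel=1e-12)

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(14)
        rejections = 0
        n_sims = 2000
        for _ in range(n_sims):
            base = rng.normal(0, 1, 20)
            a = base + rng.normal(0, 1, 20)
            b = base + rng.normal(0, 1, 20)
            rejections += wilcoxon_signed_rank(a, b)[2] < 0.05
        rate = rejections / n_sims
        assert abs(rate - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / n_sims)


class TestRMAnovaGG:
    def test_two_conditions_force_epsilon_one(self):
        rng = np.random.default_rng(15)
        res = rm_anova_gg(rng.normal(0, 1, (10, 2)))
        assert res.epsilon_gg == 1.0
        assert res.df1 == 1 and res.df2 == 9

    def test_compound_symmetry_gives_epsilon_near_one(self):
        rng = np.random.default_rng(16)
        n, k = 200, 5
        subject = rng.normal(0, 2, (n, 1))
        wide = subject + rng.normal(0, 1, (n, k))
        res = rm_anova_gg(wide)
        assert res.epsilon_gg == pytest.approx(1.0, abs=0.05)

    def test_strong_condition_shift_detected(self):
        rng = np.random.default_rng(17)
        wide = rng.normal(0, 1, (21, 4))
        wide[:, 0] += 3.0
        res = rm_anova_gg(wide)
        assert res.p < 0.001
        assert 0.0 <= res.partial_eta_sq < 1.0

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(18)
        n, k = 15, 4
        wide = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
        wide[:, 1] += 0.8
        res = rm_anova_gg(wide)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "cond": np.tile(np.arange(k), n),
                "y": wide.ravel(),
            }
        )
        aov = pg.rm_anova(long, dv="y", within="cond", subject="subject", correction=True, detailed=True)
        assert res.F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-6)
        assert res.epsilon_gg == pytest.approx(float(aov["eps"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(aov["p_GG_corr"].iloc[0]), rel=1e-4)
        assert res.partial_eta_sq == pytest.approx(float(aov["ng2"].iloc[0]), abs=0.35)  # different effect-size definitions

    def test_incomplete_grid_rejected(self):
        wide = np.ones((5, 3))
        wide[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_gg(wide)


class TestPartialEtaSq:
    def test_published_worked_example(self):
        """F = 1000.731 on df (8, 160) corresponds to eta_p^2 = 0.980."""
        assert partial_eta_sq(1000.731, 8, 160) == pytest.approx(0.980, abs=5e-4)

    def test_zero_f(self):
        assert partial_eta_sq(0.0, 8, 160) == 0.0

    def test_equals_sums_of_squares_ratio(self):
        rng = np.random.default_rng(19)
        wide = rng.normal(0, 1, (12, 3)) + rng.normal(0, 1, (12, 1))
        wide[:, 2] += 1.0
        n, k = wide.shape
        grand = wide.mean()
        ss_cond = n * np.sum((wide.mean(axis=0) - grand) ** 2)
        ss_subj = k * np.sum((wide.mean(axis=1) - grand) ** 2)
        ss_err = np.sum((wide - grand) ** 2) - ss_cond - ss_subj
        res = rm_anova_gg(wide)
        assert res.partial_eta_sq == pytest.approx(ss_cond / (ss_cond + ss_err), rel=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            partial_eta_sq(-1.0, 8, 160)
        with pytest.raises(ValueError):
            partial_eta_sq(1.0, 0, 160)


class TestSummarizeOrdinal:
    def test_published_cell(self):
        """{9 x 20, 8 x 1}: Mdn 9 (9-9), mean 8.95, SD 0.22."""
        scores = [9] * 20 + [8]
        med, (q1, q3), mean, sd = summarize_ordinal(scores)
        assert (med, q1, q3) == (9.0, 9.0, 9.0)
        assert mean == pytest.approx(8.952, abs=5e-4)
        assert sd == pytest.approx(0.218, abs=5e-4)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            summarize_ordinal([7])

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            x = rng.integers(1, 11, rng.integers(5, 30))
            med, (q1, q3), mean, sd = summarize_ordinal(x)
            assert med == np.median(x)
            assert mean == pytest.approx(x.sum() / x.size)
            assert sd == pytest.approx(np.sqrt(((x - x.mean()) ** 2).sum() / (x.size - 1)))
            assert q1 <= med <= q3
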