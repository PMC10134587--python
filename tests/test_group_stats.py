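"""Statistical battery: agreement with independent oracles (scipy /
statsmodels / raw-data recomputation), published-value reproduction, and
calibration properties."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from kbcdss.group_stats import (
    GroupSummary,
    ancova_one_covariate,
    ancova_power,
    ancova_sample_size,
    anova_from_summary,
    inflate_for_dropout,
    mcnemar_bowker,
    msw_from_summary,
    pearson_chi_square,
    scheffe_posthoc,
)

POSTTEST_N = {"control": 206, "cdv": 203, "bade": 198}


def two_by_three(counts):
    ns = list(POSTTEST_N.values())
    return [counts, [n - c for n, c in zip(ns, counts)]]


class TestChiSquare:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([155, 191, 172], 29.57),  # posttest compliance
            ([63, 126, 98], 41.24),  # posttest true positives
            ([106, 60, 76], 20.72),  # posttest false negatives
            ([37, 17, 24], 8.53),  # posttest false positives
        ],
    )
    def test_published_posttest_tables(self, counts, expected):
        result = pearson_chi_square(two_by_three(counts))
        assert result.statistic == pytest.approx(expected, abs=0.005)
        assert result.df == 2

    def test_identical_row_proportions_give_zero(self):
        assert pearson_chi_square([[10, 20, 30], [20, 40, 60]]).statistic == pytest.approx(0)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi_square([[0, 5], [0, 7]])

    def test_permutation_invariance_and_scipy_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(1, 30, size=(2, 3))
            ours = pearson_chi_square(t)
            chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
            assert ours.statistic == pytest.approx(chi2)
            assert ours.p_value == pytest.approx(p)
            perm = t[::-1][:, rng.permutation(3)]
            assert pearson_chi_square(perm).statistic == pytest.approx(ours.statistic)

    def test_exhaustive_small_2x2_against_direct_formula(self):
        for a, b, c, d in itertools.product(range(1, 6), repeat=4):
            t = np.array([[a, b], [c, d]], float)
            n = t.sum()
            e = np.outer(t.sum(1), t.sum(0)) / n
            brute = ((t - e) ** 2 / e).sum()
            assert pearson_chi_square(t).statistic == pytest.approx(brute)


class TestMcNemarBowker:
    def test_two_by_two_discordant(self):
        r = mcnemar_bowker([[30, 10], [2, 40]])
        assert r.statistic == pytest.approx((10 - 2) ** 2 / 12)
        assert r.df == 1

    def test_balanced_discordance_is_zero(self):
        assert mcnemar_bowker([[5, 7], [7, 9]]).statistic == 0

    def test_symmetric_3x3(self):
        t = [[10, 3, 4], [3, 12, 5], [4, 5, 9]]
        r = mcnemar_bowker(t)
        assert r.statistic == 0 and r.df == 3

    def test_all_concordant_undefined(self):
        with pytest.raises(ValueError):
            mcnemar_bowker([[10, 0], [0, 12]])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_bowker([[1, 2, 3], [4, 5, 6]])

    def test_statsmodels_oracle(self):
        from statsmodels.stats.contingency_tables import SquareTable, mcnemar

        rng = np.random.default_rng(5)
        for k in (2, 3, 4):
            t = rng.integers(1, 20, size=(k, k))
            ours = mcnemar_bowker(t)
            if k == 2:
                ref = mcnemar(t, exact=False, correction=False)
                assert ours.statistic == pytest.approx(float(ref.statistic))
                assert ours.p_value == pytest.approx(float(ref.pvalue))
            else:
                ref = SquareTable(t).symmetry(method="bowker")
                assert ours.statistic == pytest.approx(float(ref.statistic))
                assert ours.p_value == pytest.approx(float(ref.pvalue))


class TestAnovaFromSummary:
    def test_published_age_f(self):
        groups = [
            GroupSummary(206, 21.30, 1.44, "control"),
            GroupSummary(203, 21.59, 1.49, "cdv"),
            GroupSummary(198, 21.53, 2.00, "bade"),
        ]
        r = anova_from_summary(groups)
        assert r.statistic == pytest.approx(1.74, rel=0.005)
        assert r.df == (2, 604)

    def test_identical_means_give_zero(self):
        groups = [GroupSummary(10, 5.0, 1.0), GroupSummary(12, 5.0, 2.0)]
        assert anova_from_summary(groups).statistic == 0

    def test_matches_raw_data_anova(self):
        rng = np.random.default_rng(9)
        samples = [rng.normal(loc, 1.2, size=n) for loc, n in ((0, 15), (0.5, 20), (1.0, 12))]
        summaries = [
            GroupSummary(len(x), float(x.mean()), float(x.std(ddof=1))) for x in samples
        ]
        ours = anova_from_summary(summaries)
        f_ref, p_ref = sps.f_oneway(*samples)
        assert ours.statistic == pytest.approx(f_ref)
        assert ours.p_value == pytest.approx(p_ref)

    def test_degenerate_zero_within_variance(self):
        groups = [GroupSummary(5, 1.0, 0.0), GroupSummary(5, 2.0, 0.0)]
        r = anova_from_summary(groups)
        assert np.isinf(r.statistic) and r.p_value == 0


class TestAncova:
    def _simulate(self, rng, n=60, effect=0.8, slope=0.5):
        group = np.repeat(["a", "b", "c"], n // 3)
        cov = rng.normal(size=n)
        shift = {"a": 0.0, "b": effect, "c": 2 * effect}
        y = slope * cov + np.array([shift[g] for g in group]) + rng.normal(size=n)
        return group, cov, y

    def test_matches_statsmodels_ols_oracle(self):
        import pandas as pd
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(21)
        group, cov, y = self._simulate(rng)
        ours = ancova_one_covariate(group, cov, y)
        df = pd.DataFrame({"y": y, "x": cov, "g": group})
        fit = smf.ols("y ~ x + C(g, Sum)", data=df).fit()
        tab = anova_lm(fit, typ=3)
        assert ours.statistic == pytest.approx(float(tab.loc["C(g, Sum)", "F"]))
        assert ours.p_value == pytest.approx(float(tab.loc["C(g, Sum)", "PR(>F)"]))

    def test_orthogonal_zero_slope_covariate_matches_anova(self):
        rng = np.random.default_rng(22)
        group, _, y = self._simulate(rng, slope=0.0)
        cov = rng.normal(size=len(y))  # independent noise, no slope
        f_ancova = ancova_one_covariate(group, cov, y).statistic
        samples = [y[group == g] for g in "abc"]
        f_anova, _ = sps.f_oneway(*samples)
        assert f_ancova == pytest.approx(f_anova, rel=0.15)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            ancova_one_covariate(["a", "a", "b", "b"], [1, 1, 1, 1], [1, 2, 3, 4])

    def test_permutation_calibration(self):
        """Under group permutation, the observed F should exceed the 0.05
        critical value about 5% of the time."""
        rng = np.random.default_rng(23)
        group, cov, y = self._simulate(rng, effect=0.0)
        crit = sps.f.isf(0.05, 2, len(y) - 4)
        rejections = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(len(y))
            f = ancova_one_covariate(group[perm], cov, y).statistic
            rejections += f > crit
        assert rejections / n_perm == pytest.approx(0.05, abs=0.02)


class TestScheffe:
    def _ease_of_use(self):
        return [
            GroupSummary(206, 1.03, 1.36, "a"),
            GroupSummary(203, 2.80, 1.27, "b"),
            GroupSummary(198, 2.47, 1.27, "c"),
        ]

    def test_published_perceived_ease_of_use_ordering(self):
        groups = self._ease_of_use()
        result = scheffe_posthoc(groups, msw_from_summary(groups))
        assert result.ordering() == "a < c < b"
        assert all(c.significant for c in result.comparisons)

    def test_identical_groups_no_significant_pairs(self):
        groups = [GroupSummary(50, 2.0, 1.0, lab) for lab in "abc"]
        result = scheffe_posthoc(groups, msw_from_summary(groups))
        assert not any(c.significant for c in result.comparisons)
        assert result.ordering() == ""

    def test_two_group_reduction_matches_pooled_t_test(self):
        # with k=2 the Scheffe criterion reduces to t^2 > F_crit(1, N-2)
        groups = [GroupSummary(20, 1.0, 1.1, "a"), GroupSummary(25, 1.9, 0.9, "b")]
        msw = msw_from_summary(groups)
        (comp,) = scheffe_posthoc(groups, msw).comparisons
        se = np.sqrt(msw * (1 / 20 + 1 / 25))
        t_sq = ((1.0 - 1.9) / se) ** 2
        assert comp.statistic == pytest.approx(t_sq)
        assert comp.critical == pytest.approx(float(sps.f.isf(0.05, 1, 43)))

    def test_partial_significance_rendering(self):
        # control far below two statistically indistinguishable arms
        groups = [
            GroupSummary(60, 1.0, 1.0, "a"),
            GroupSummary(60, 2.5, 1.0, "b"),
            GroupSummary(60, 2.45, 1.0, "c"),
        ]
        result = scheffe_posthoc(groups, msw_from_summary(groups))
        assert result.ordering() == "a < b; a < c"


class TestSampleSize:
    def test_power_monotone_in_n_and_f(self):
        powers_n = [ancova_power(0.2, n, 0.05, 3, 1) for n in (60, 120, 240, 480)]
        assert all(np.diff(powers_n) > 0)
        powers_f = [ancova_power(f, 200, 0.05, 3, 1) for f in (0.1, 0.2, 0.3, 0.4)]
        assert all(np.diff(powers_f) > 0)

    def test_solution_is_minimal(self):
        res = ancova_sample_size(0.2, 0.05, 0.80, 3, 1)
        assert ancova_power(0.2, res.n_total, 0.05, 3, 1) >= 0.80
        assert ancova_power(0.2, res.n_total - 1, 0.05, 3, 1) < 0.80
        assert res.n_per_group == -(-res.n_total // 3)

    def test_tiny_power_hits_df_boundary(self):
        res = ancova_sample_size(0.5, 0.05, 0.06, 3, 1)
        assert res.n_total == 3 + 1 + 2  # minimal N with positive error df

    def test_doubling_f_roughly_quarters_n(self):
        n_small = ancova_sample_size(0.2, 0.05, 0.90, 3, 1).n_total
        n_big = ancova_sample_size(0.4, 0.05, 0.90, 3, 1).n_total
        assert n_small / n_big == pytest.approx(4, rel=0.15)

    def test_monte_carlo_power_agrees_with_noncentral_f(self):
        """Simulated rejection rate at the solved N matches the analytic
        noncentral-F power."""
        f_effect, alpha, k = 0.4, 0.05, 3
        res = ancova_sample_size(f_effect, alpha, 0.80, k, 1)
        n = res.n_total - res.n_total % k  # balanced groups
        per = n // k
        # means with between-group sd f*sigma: lambda = f^2 n
        d = f_effect * np.sqrt(3 / 2)
        means = np.array([-d, 0.0, d])
        rng = np.random.default_rng(17)
        group = np.repeat(list("abc"), per)
        crit = sps.f.isf(alpha, k - 1, n - k - 1)
        reps, hits = 800, 0
        for _ in range(reps):
            cov = rng.normal(size=n)
            y = np.repeat(means, per) + rng.normal(size=n)
            hits += ancova_one_covariate(group, cov, y).statistic > crit
        predicted = ancova_power(f_effect, n, alpha, k, 1)
        assert hits / reps == pytest.approx(predicted, abs=0.05)


class TestDropoutInflation:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((180, 0.15, 3), (212, 636)),
            ((100, 0.0, 3), (100, 300)),
            ((85, 0.15, 1), (100, 100)),
        ],
    )
    def test_examples(self, args, expected):
        assert inflate_for_dropout(*args) == expected

    def test_rate_of_one_rejected(self):
        with pytest.raises(ValueError):
            inflate_for_dropout(100, 1.0, 3)
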