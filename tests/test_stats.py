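"""Statistical procedures: chi-square, ANOVA, t-tests, power, correlation.

Mixed-ANOVA expected values for the small fixture were frozen from an
independent computation of the classical split-plot decomposition
(cross-checked against R's aov); larger random designs are compared with
pingouin at run time.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rewardbias.stats import (
    PowerSpec,
    StatsError,
    age_association,
    code_genotypes,
    cohens_d,
    contingency_chisq,
    hwe_chisq,
    independent_t,
    mixed_anova,
    one_sample_t,
    oneway_anova,
    oneway_anova_summary,
    pairwise_corrected,
    power_two_sample,
)


class TestHWE:
    def test_exact_hwe_proportions_give_zero(self):
        r = hwe_chisq(25, 50, 25)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_study_counts(self):
        """Brute-force expected counts from genotype totals 23/62/79."""
        r = hwe_chisq(23, 62, 79)
        assert r.statistic == pytest.approx(3.4058, abs=1e-3)
        assert r.df == (1.0,)

    def test_maximal_heterozygote_excess(self):
        r = hwe_chisq(0, 100, 0)
        assert r.statistic == pytest.approx(100.0)

    def test_monomorphic_raises(self):
        with pytest.raises(StatsError):
            hwe_chisq(0, 0, 50)


class TestContingency:
    def test_independence_gives_zero(self):
        r = contingency_chisq([[10, 10], [10, 10]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_site_by_genotype_counts(self):
        r = contingency_chisq([[16, 50, 64], [7, 12, 15]])
        assert r.statistic == pytest.approx(1.5355, abs=1e-3)
        assert r.df == (2.0,)

    def test_gender_by_genotype_counts(self):
        r = contingency_chisq([[10, 33, 29], [13, 30, 50]])
        assert r.p_value == pytest.approx(0.174, abs=1e-3)

    def test_zero_marginal_raises(self):
        with pytest.raises(StatsError):
            contingency_chisq([[0, 0], [5, 5]])


class TestOneWay:
    def test_identical_groups(self):
        r = oneway_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)
        assert r.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_summary_matches_raw(self, rng):
        groups = [rng.normal(m, 1.0, size=n) for m, n in [(0, 11), (0.4, 17), (0.9, 9)]]
        raw = oneway_anova(groups)
        summ = oneway_anova_summary(
            [len(g) for g in groups],
            [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups],
        )
        assert summ.statistic == pytest.approx(raw.statistic, rel=1e-12)
        assert summ.p_value == pytest.approx(raw.p_value, rel=1e-12)

    def test_age_summary_from_descriptive_table(self):
        """Cohort age moments: n=(23, 62, 79), near-identical means."""
        r = oneway_anova_summary(
            [23, 62, 79], [22.70, 22.21, 22.23], [3.698, 4.315, 4.717]
        )
        assert r.p_value == pytest.approx(0.90, abs=0.02)
        assert r.df == (2.0, 161.0)

    def test_two_groups_equal_t_squared(self, rng):
        a, b = rng.normal(0, 1, 14), rng.normal(0.5, 1, 9)
        f = oneway_anova([a, b])
        t = independent_t(a, b)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert f.p_value == pytest.approx(t.p_value, rel=1e-10)


MIXED_Y = np.array(
    [
        [0.2, 0.5, 0.9],
        [0.1, 0.4, 0.6],
        [0.3, 0.3, 0.5],
        [0.0, 0.2, 0.4],
        [0.5, 0.6, 0.7],
        [0.4, 0.8, 1.0],
    ]
)
MIXED_GROUPS = ["AA", "AA", "AG", "AG", "GG", "GG"]


class TestMixedAnova:
    def test_small_fixture_decomposition(self):
        """3 groups x 2 subjects x 3 blocks; frozen split-plot decomposition."""
        res = mixed_anova(MIXED_Y, MIXED_GROUPS)
        assert res["between"].statistic == pytest.approx(6.045455, abs=1e-5)
        assert res["between"].df == (2.0, 3.0)
        assert res["between"].p_value == pytest.approx(0.088636, abs=1e-5)
        assert res["within"].statistic == pytest.approx(24.142857, abs=1e-5)
        assert res["within"].p_value == pytest.approx(0.00135, abs=1e-5)
        assert res["interaction"].statistic == pytest.approx(1.142857, abs=1e-5)
        assert res["interaction"].df == (4.0, 6.0)
        assert res["interaction"].p_value == pytest.approx(0.42002, abs=1e-5)

    def test_unbalanced_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        ns = [8, 13, 21]
        groups = sum([[g] * m for g, m in zip("ABC", ns)], [])
        y = rng.normal(size=(sum(ns), 3)) + np.repeat([0.0, 0.3, 0.6], ns)[:, None]
        mine = mixed_anova(y, groups)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(sum(ns)), 3),
                "group": np.repeat(groups, 3),
                "block": np.tile(np.arange(3), sum(ns)),
                "y": y.ravel(),
            }
        )
        ref = pg.mixed_anova(
            data=long, dv="y", within="block", subject="subject", between="group"
        ).set_index("Source")
        assert mine["between"].statistic == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert mine["within"].statistic == pytest.approx(ref.loc["block", "F"], rel=1e-9)
        assert mine["interaction"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert mine["between"].effect_size == pytest.approx(ref.loc["group", "np2"], rel=1e-9)

    def test_covariate_adjustment_matches_pingouin_ancova(self, rng):
        pg = pytest.importorskip("pingouin")
        ns = [10, 12, 15]
        groups = sum([[g] * m for g, m in zip("ABC", ns)], [])
        y = rng.normal(size=(sum(ns), 3))
        cov = rng.normal(size=sum(ns))
        mine = mixed_anova(y, groups, covariate=cov)["between"]
        ref = pg.ancova(
            data=pd.DataFrame({"m": y.mean(axis=1), "g": groups, "c": cov}),
            dv="m", between="g", covar="c",
        ).set_index("Source")
        assert mine.statistic == pytest.approx(ref.loc["g", "F"], rel=1e-9)
        assert mine.p_value == pytest.approx(ref.loc["g", "p_unc"], rel=1e-9)

    def test_large_separation_is_decisive(self, rng):
        y = rng.normal(size=(60, 3))
        y[:20] += 10.0
        groups = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
        assert mixed_anova(y, groups)["between"].p_value < 1e-6

    def test_missing_cells_raise(self):
        y = MIXED_Y.copy()
        y[0, 0] = np.nan
        with pytest.raises(StatsError):
            mixed_anova(y, MIXED_GROUPS)

    def test_single_subject_group_raises(self):
        with pytest.raises(StatsError):
            mixed_anova(MIXED_Y, ["AA"] + ["AG"] * 2 + ["GG"] * 3)

    def test_greenhouse_geisser_shrinks_df(self, rng):
        y = rng.normal(size=(30, 4))
        y[:, 0] += y[:, 1] * 0.9  # induce nonsphericity
        groups = ["A"] * 15 + ["B"] * 15
        plain = mixed_anova(y, groups)["within"]
        gg = mixed_anova(y, groups, sphericity_correction="greenhouse-geisser")["within"]
        assert gg.df[0] < plain.df[0]
        assert gg.statistic == pytest.approx(plain.statistic)


class TestTTests:
    def test_one_sample_symmetric(self):
        r = one_sample_t([-2.0, -1.0, 1.0, 2.0])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_one_sample_hand_value(self):
        r = one_sample_t([1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert r.df == (2.0,)

    def test_one_sample_zero_variance_raises(self):
        with pytest.raises(StatsError):
            one_sample_t([1.0, 1.0, 1.0])

    def test_cohens_d_identical_groups(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_cohens_d_unit_separation(self, rng):
        a = rng.normal(1.0, 1.0, 50000)
        b = rng.normal(0.0, 1.0, 50000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.03)

    def test_cohens_d_hand_value(self):
        assert cohens_d([0.0, 1.0, 2.0], [2.0, 3.0, 4.0]) == pytest.approx(-2.0)
        r = independent_t([0.0, 1.0, 2.0], [2.0, 3.0, 4.0])
        assert r.effect_size == pytest.approx(-2.0)
        assert r.df == (4.0,)


class TestPairwise:
    def test_identical_groups_corrected_to_one(self):
        g = {"a": [1.0, 2.0, 3.1], "b": [1.0, 2.0, 3.1], "c": [1.0, 2.0, 3.1]}
        for r in pairwise_corrected(g):
            assert r.p_value == 1.0
            assert r.correction == "bonferroni"

    def test_correction_multiplies_by_comparisons(self, rng):
        g = {k: rng.normal(size=8) for k in "abc"}
        corrected = {r.name: r.p_value for r in pairwise_corrected(g)}
        for (l1, l2) in [("a", "b"), ("a", "c"), ("b", "c")]:
            raw = independent_t(g[l1], g[l2]).p_value
            assert corrected[f"{l1}_vs_{l2}"] == pytest.approx(min(1.0, raw * 3))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_corrected_never_below_raw(self, seed):
        rng = np.random.default_rng(seed)
        g = {k: rng.normal(size=6) for k in "abc"}
        raws = {
            f"{l1}_vs_{l2}": independent_t(g[l1], g[l2]).p_value
            for l1, l2 in [("a", "b"), ("a", "c"), ("b", "c")]
        }
        for r in pairwise_corrected(g):
            assert r.p_value >= raws[r.name] - 1e-15


class TestPower:
    def test_study_power_values(self):
        """Analytic one-sided power at the study's group sizes 85/79."""
        assert round(power_two_sample(PowerSpec(0.38, 85, 79)), 2) == 0.78
        assert round(power_two_sample(PowerSpec(0.37, 85, 79)), 2) == 0.76

    def test_null_effect_gives_alpha(self):
        assert power_two_sample(PowerSpec(0.0, 30, 30, alpha=0.05)) == pytest.approx(
            0.05, abs=1e-9
        )

    def test_monotone_in_d_n_alpha(self):
        base = power_two_sample(PowerSpec(0.4, 40, 40))
        assert power_two_sample(PowerSpec(0.6, 40, 40)) > base
        assert power_two_sample(PowerSpec(0.4, 80, 80)) > base
        assert power_two_sample(PowerSpec(0.4, 40, 40, alpha=0.10)) > base

    def test_normal_approximation_close_for_large_df(self):
        for d in (0.2, 0.4, 0.6):
            nct = power_two_sample(PowerSpec(d, 60, 60, method="noncentral-t"))
            norm = power_two_sample(PowerSpec(d, 60, 60, method="normal-approximation"))
            assert abs(nct - norm) < 0.01

    def test_two_sided_less_powerful_than_one_sided(self):
        one = power_two_sample(PowerSpec(0.4, 50, 50, tails="one-sided"))
        two = power_two_sample(PowerSpec(0.4, 50, 50, tails="two-sided"))
        assert two < one


class TestCorrelation:
    def test_perfect_linear(self):
        r = age_association([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        assert r.statistic == pytest.approx(1.0)

    def test_hand_fixture(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 2.0])
        expected = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        r = age_association(x, y)
        assert r.statistic == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(StatsError):
            age_association([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGenotypeCoding:
    def test_dominant_is_union_complement_of_additive(self):
        genos = ["AA", "AG", "GG", "AG", "GG", "AA"]
        add = code_genotypes(genos, "additive")
        dom = code_genotypes(genos, "dominant")
        assert (dom["AA/AG"] == (add["AA"] | add["AG"])).all()
        assert (dom["GG"] == add["GG"]).all()
        assert (dom["AA/AG"] ^ dom["GG"]).all()

    def test_unknown_label_raises(self):
        with pytest.raises(StatsError):
            code_genotypes(["AA", "XY"], "additive")
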