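"""Inference layer: genetics utilities, nested comparisons, the hierarchy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rewardnet as rn
from rewardnet.stats import (simulate_null_rejection_rate, ALPHA_NETWORK,
                             ALPHA_NODE)


class TestMaf:
    @pytest.mark.parametrize("counts,expected", [
        ((116, 170, 61), 0.42),
        ((249, 89, 9), 0.15),
        ((100, 0, 0), 0.0),
    ])
    def test_examples(self, counts, expected):
        assert rn.minor_allele_frequency(counts) == pytest.approx(expected,
                                                                  abs=0.005)

    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(st.integers(0, 500), st.integers(0, 500),
                     st.integers(0, 500)).filter(lambda c: sum(c) > 0))
    def test_folded_and_label_swap_invariant(self, counts):
        maf = rn.minor_allele_frequency(counts)
        assert 0.0 <= maf <= 0.5
        assert maf == pytest.approx(
            rn.minor_allele_frequency(counts[::-1]), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            rn.minor_allele_frequency((0, 0, 0))
        with pytest.raises(ValueError):
            rn.minor_allele_frequency((-1, 2, 3))


class TestHwe:
    def test_exact_hwe_proportions_give_zero(self):
        chi2, p = rn.hwe_chi2((25, 50, 25))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_departure(self):
        """(30,40,30): allele freqs 0.5/0.5, expected (25,50,25),
        chi2 = 25/25 + 100/50 + 25/25 = 4."""
        chi2, p = rn.hwe_chi2((30, 40, 30))
        assert chi2 == pytest.approx(4.0, abs=1e-12)
        assert 0.0 < p < 0.05

    def test_monomorphic_locus_raises(self):
        with pytest.raises(ValueError):
            rn.hwe_chi2((100, 0, 0))


class TestGenotypeGroups:
    def test_fto_additive_coding(self):
        g = pd.Series(["TT", "AT", "AA", "TA"])
        assert rn.genotype_groups(g, "fto").tolist() == [0, 1, 2, 1]

    def test_taq1a_carrier_coding(self):
        g = pd.Series(["TT", "AT", "AA"])
        assert rn.genotype_groups(g, "taq1a").tolist() == [0, 1, 1]

    def test_unknown_genotype_raises(self):
        with pytest.raises(ValueError):
            rn.genotype_groups(pd.Series(["GG"]), "fto")


class TestPower:
    def test_study_design_power(self):
        assert rn.power_two_sample(150, 197, 0.44, 0.05) == pytest.approx(
            0.98, abs=0.005)

    def test_null_effect_power_equals_alpha(self):
        assert rn.power_two_sample(50, 50, 0.0, 0.05) == pytest.approx(
            0.05, abs=1e-6)

    def test_large_effect_power_approaches_one(self):
        assert rn.power_two_sample(50, 50, 5.0, 0.05) == pytest.approx(
            1.0, abs=1e-6)

    def test_monotone_in_n_and_effect(self):
        base = rn.power_two_sample(30, 30, 0.5)
        assert rn.power_two_sample(60, 30, 0.5) > base
        assert rn.power_two_sample(30, 60, 0.5) > base
        assert rn.power_two_sample(30, 30, 0.8) > base
        assert rn.power_two_sample(30, 30, -0.5) == pytest.approx(base)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rn.power_two_sample(1, 50, 0.5)
        with pytest.raises(ValueError):
            rn.power_two_sample(50, 50, 0.5, alpha=1.5)


def test_bonferroni_thresholds():
    assert rn.bonferroni(0.05, 4) == 0.0125
    assert rn.bonferroni(0.05, 10) == 0.005
    assert rn.bonferroni(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        rn.bonferroni(0.05, 0)


def test_bmi_sensitivity_fence():
    """(20,22,24,26,60): Q1=22, Q3=26, upper fence 26 + 1.5*4 = 32."""
    mask = rn.bmi_outlier_mask([20, 22, 24, 26, 60], k=1.5)
    assert mask.tolist() == [False, False, False, False, True]


def _toy_data(n=120, seed=0, beta=0.0, noise=1.0):
    rng = np.random.default_rng(seed)
    age = rng.uniform(20, 60, n)
    sex = np.where(rng.random(n) < 0.5, "f", "m")
    x = rng.normal(25, 3, n)
    y = 1.0 + 0.01 * age + 0.2 * (sex == "m") + beta * x \
        + rng.normal(0, noise, n)
    return pd.DataFrame({"age": age, "sex": sex, "x": x, "y": y})


class TestCompareNested:
    def test_perfect_fit_drives_p_to_zero(self):
        df = _toy_data(beta=0.5, noise=0.0)
        res = rn.compare_nested(df, "y ~ age + C(sex) + x", "y ~ age + C(sex)")
        assert res.comparison_p < 1e-12
        assert res.estimate == pytest.approx(0.5, abs=1e-10)

    def test_f_equals_t_squared_for_single_added_predictor(self):
        for seed in range(10):
            df = _toy_data(seed=seed, beta=0.1)
            res = rn.compare_nested(df, "y ~ age + C(sex) + x",
                                    "y ~ age + C(sex)", focal="x")
            import statsmodels.formula.api as smf
            t = smf.ols("y ~ age + C(sex) + x", df).fit().tvalues["x"]
            assert res.stat == pytest.approx(t**2, rel=1e-10)
            assert res.method == "F"

    def test_ci_contains_estimate(self):
        res = rn.compare_nested(_toy_data(beta=0.2), "y ~ age + C(sex) + x",
                                "y ~ age + C(sex)")
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_lrt_method(self):
        df = _toy_data(beta=0.3)
        res = rn.compare_nested(df, "y ~ age + C(sex) + x", "y ~ age + C(sex)",
                                method="LRT")
        assert res.method == "LRT"
        assert res.stat > 0
        assert res.df_den is None

    def test_listwise_missing_reduces_n(self):
        df = _toy_data(n=100)
        df.loc[:9, "x"] = np.nan
        res = rn.compare_nested(df, "y ~ age + C(sex) + x", "y ~ age + C(sex)")
        assert res.n == 90

    def test_collinear_design_raises_with_term_names(self):
        df = _toy_data()
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(ValueError, match="collinear"):
            rn.compare_nested(df, "y ~ x + x2", "y ~ x")

    def test_non_nested_raises(self):
        df = _toy_data()
        with pytest.raises(ValueError, match="nested"):
            rn.compare_nested(df, "y ~ x", "y ~ age")

    def test_adding_noise_covariates_never_increases_rss(self):
        rng = np.random.default_rng(1)
        df = _toy_data(beta=0.2)
        df["noise1"] = rng.normal(size=len(df))
        df["noise2"] = rng.normal(size=len(df))
        import statsmodels.formula.api as smf
        rss_small = smf.ols("y ~ x", df).fit().ssr
        rss_big = smf.ols("y ~ x + noise1 + noise2", df).fit().ssr
        assert rss_big <= rss_small + 1e-10


@pytest.fixture(scope="module")
def hierarchy():
    cohort = rn.make_cohort(rn.CohortSpec(n=347, seed=42))
    return rn.run_model_hierarchy(cohort)


class TestHierarchy:

    def test_bonferroni_levels_emitted(self, hierarchy):
        assert hierarchy.alpha_network == 0.0125
        assert hierarchy.alpha_node == 0.005

    def test_model1_row_per_network_metric(self, hierarchy):
        m1 = hierarchy.results.query("family == 'model1'")
        assert sorted(m1["outcome"]) == ["fa_cc", "fa_cs", "nos_cc", "nos_cs"]
        assert m1["estimate"].notna().all()
        assert ((m1["ci_low"] <= m1["estimate"])
                & (m1["estimate"] <= m1["ci_high"])).all()

    def test_genotype_interaction_tested_by_f_and_chi2(self, hierarchy):
        m34 = hierarchy.results.query("family == 'model3_vs_4'")
        assert sorted(m34["method"]) == ["F", "LRT"]

    def test_fto_contrasts_reported(self, hierarchy):
        terms = hierarchy.results.query("family == 'model4_terms'")["term"]
        assert set(terms) == {"C(fto)[T.1]", "C(fto)[T.2]", "taq1a"}

    def test_planted_fto_effect_detected(self, hierarchy):
        """The generator plants an additive FTO effect on BMI of ~1 kg/m^2
        per allele; at n=347 the Model-4 comparison should see it."""
        m4 = hierarchy.results.query("family == 'model4'").iloc[0]
        assert m4["comparison_p"] < 0.05

    def test_genotype_bmi_adjusted_variant_present(self, hierarchy):
        adj = hierarchy.results.query("family == 'model6_terms_bmi_adj'")
        assert len(adj) == 3 * 4  # three contrasts per metric

    def test_sensitivity_excludes_upper_bmi_outliers_only(self, hierarchy):
        sens = hierarchy.results.query("family == 'model1_bmi_sensitivity'")
        assert len(sens) == 4
        assert (sens["n"] + sens["n_excluded"] == 347).all()

    def test_exploratory_interactions_cover_strength_metrics(self, hierarchy):
        expl = hierarchy.results.query("family == 'exploratory_interaction'")
        assert set(expl["outcome"]) == {"fa_cs", "nos_cs"}
        assert set(expl["term"]) == {"C(sex):bmi", "age:bmi"}

    def test_listwise_ns_vary_with_missingness(self, hierarchy):
        """Model 2 uses the questionnaire covariates, so its n drops below
        the Model-1 n (missing smoking/education/CES-D)."""
        r = hierarchy.results
        n1 = r.query("family == 'model1'")["n"].max()
        m2 = r.query("family == 'model2' or family == 'model2_nodewise'")
        if len(m2):
            assert (m2["n"] < n1).all()
        assert n1 == 347


def test_null_rejection_rate_is_calibrated_quickly():
    """Small-scale sanity check of the type-I error simulation (the full
    1000-replicate calibration runs in the acceptance suite)."""
    rate, pvals = simulate_null_rejection_rate(n=347, reps=120, seed=11)
    assert 0.0 <= rate <= 0.15
    # p-values roughly uniform: mean near 0.5
    assert abs(pvals.mean() - 0.5) < 0.1
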