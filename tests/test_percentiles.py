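"""Percentile normalization, heterozygote z-tests, carrier contrasts,
burden collapsing and variance explained."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from popreseq import percentiles as pct
from popreseq import synthetic as syn
from popreseq.config import GeneratorConfig, VariantSpec


def tiny_cohort(values, sex="F", age=45.0, study="X"):
    n = len(values)
    return pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(n)],
            "sex": sex,
            "age_at_exam": age,
            "study": study,
            "apoa1": values,
        }
    )


class TestAssignPercentiles:
    def test_three_values_definition(self):
        asn = pct.assign_percentiles(tiny_cohort([1.0, 2.0, 3.0]), "apoa1")
        np.testing.assert_allclose(
            asn["percentile"], [100 / 6, 50.0, 500 / 6], rtol=1e-12
        )

    def test_ties_share_midrank(self):
        asn = pct.assign_percentiles(tiny_cohort([1.0, 2.0, 2.0, 4.0]), "apoa1")
        p = asn["percentile"].to_numpy()
        assert p[1] == p[2] == pytest.approx(50.0)
        assert p[0] < p[1] < p[3]

    def test_small_stratum_warns_and_assigns_median(self):
        cohort = tiny_cohort([1.0, 2.0, 3.0])
        cohort.loc[2, "sex"] = "M"  # a 1-person stratum
        with pytest.warns(UserWarning, match="stratum"):
            asn = pct.assign_percentiles(cohort, "apoa1")
        assert asn["percentile"].iloc[2] == 50.0

    def test_null_cohort_pooled_percentiles_uniform(self, null_cohort):
        cohort, _ = null_cohort
        p = pct.assign_percentiles(cohort, "apoa1")["percentile"].to_numpy()
        ks = stats.kstest(p / 100.0, "uniform").statistic
        assert ks < 0.02
        assert abs(p.mean() - 50.0) < 0.5

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-50.0, 50.0),
    )
    def test_invariance_under_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(31)
        values = rng.normal(140, 30, size=40)
        base = pct.assign_percentiles(tiny_cohort(values), "apoa1")
        transformed = pct.assign_percentiles(
            tiny_cohort(np.exp(scale * values / 100.0) + shift), "apoa1"
        )
        np.testing.assert_allclose(
            base["percentile"], transformed["percentile"], rtol=1e-12
        )

    def test_missing_trait_rejected(self, null_cohort):
        with pytest.raises(KeyError):
            pct.assign_percentiles(null_cohort[0], "nope")


class TestHeterozygoteZTest:
    def test_single_carrier_at_median(self):
        r = pct.heterozygote_ztest([50.0])
        assert r.z == 0.0 and r.p == pytest.approx(1.0)

    def test_four_carriers_deep_in_tail(self):
        # (3 - 50) / sqrt((10000/12)/4) = -3.2565
        r = pct.heterozygote_ztest([3.0] * 4)
        assert r.z == pytest.approx(-3.2565, abs=1e-3)
        assert r.p == pytest.approx(0.00113, abs=5e-5)

    def test_nine_carriers_not_significant(self):
        r = pct.heterozygote_ztest([62.0] * 9)
        assert r.z == pytest.approx(1.247, abs=1e-3)
        assert r.p == pytest.approx(0.212, abs=2e-3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pct.heterozygote_ztest([])

    def test_type_one_error_calibrated(self, null_cohort):
        # under the null, rejection rate at the 5% level stays within
        # binomial 3 SE for carrier-set sizes 5, 10 and 50
        cohort, _ = null_cohort
        p = pct.assign_percentiles(cohort, "apoa1")["percentile"].to_numpy()
        rng = np.random.default_rng(17)
        reps = 400
        for k in (5, 10, 50):
            rejections = sum(
                pct.heterozygote_ztest(rng.choice(p, size=k, replace=False)).p < 0.05
                for _ in range(reps)
            )
            se = np.sqrt(0.05 * 0.95 / reps)
            assert abs(rejections / reps - 0.05) < 3 * se


def fisher_two_sided_oracle(a, b, c, d):
    """Brute-force two-sided Fisher p: sum of probabilities of all tables
    with the same margins and probability <= the observed table's."""
    from scipy.special import comb

    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = comb(n, col1)

    def prob(x):
        return comb(row1, x) * comb(n - row1, col1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestCarrierContrast:
    def test_identical_groups_are_null(self):
        values = np.tile(np.arange(20, dtype=float), 2)
        cohort = tiny_cohort(values)
        cohort["flag"] = False
        out = pct.carrier_contrast(cohort, np.arange(20), continuous=["apoa1"])
        assert out["p"].iloc[0] > 0.9

    def test_fisher_matches_enumeration_oracle(self):
        cohort = tiny_cohort(np.arange(20, dtype=float))
        cohort["flag"] = [True] * 5 + [False] * 5 + [True] * 0 + [False] * 10
        out = pct.carrier_contrast(cohort, np.arange(10), binary=["flag"])
        assert out["p"].iloc[0] == pytest.approx(
            fisher_two_sided_oracle(5, 5, 0, 10), rel=1e-9
        )

    def test_lipid_effect_specific_to_lipids(self):
        # a -39 mg/dL apoA-I variant moves the apoA-I contrast but not the
        # (unaffected) triglyceride contrast, across seeds
        apoa1_sig = trig_null = used = 0
        for r in range(30):
            cfg = GeneratorConfig(
                n_individuals=5000,
                seed=7000 + r,
                variant_specs=(
                    VariantSpec("v", "NS", 12 / 10_000, apoa1_effect=-39.0),
                ),
                followup_years=0.0,
            )
            cohort, geno = syn.generate_cohort(cfg)
            carriers = geno.carriers("v")
            if carriers.size < 3:
                continue
            used += 1
            out = pct.carrier_contrast(
                cohort, carriers, continuous=["apoa1", "triglycerides"]
            ).set_index("variable")
            apoa1_sig += out.loc["apoa1", "p"] < 0.05
            trig_null += out.loc["triglycerides", "p"] >= 0.05
        assert apoa1_sig >= 0.8 * used
        assert trig_null >= 0.8 * used

    def test_unknown_variable_rejected(self, null_cohort):
        with pytest.raises(KeyError):
            pct.carrier_contrast(null_cohort[0], np.array([0]), continuous=["bmi"])


class TestBurdenCollapse:
    @pytest.fixture()
    def burden_setup(self):
        specs = (
            VariantSpec("big", "NS", 0.003, apoa1_effect=-39.0),
            VariantSpec("null1", "NS", 0.003),
            VariantSpec("null2", "NS", 0.003),
            VariantSpec("s1", "S", 0.003),
        )
        cfg = GeneratorConfig(
            n_individuals=8000, seed=55, variant_specs=specs, followup_years=0.0
        )
        cohort, geno = syn.generate_cohort(cfg)
        asn = pct.assign_percentiles(cohort, "apoa1")
        return asn, geno

    def test_single_variant_group_equals_ztest(self, burden_setup):
        asn, geno = burden_setup
        per_group, _ = pct.burden_collapse(asn, geno, {"solo": ["big"]})
        direct = pct.heterozygote_ztest(
            asn["percentile"].to_numpy()[geno.carriers("big")]
        )
        row = per_group.iloc[0]
        assert row["z"] == pytest.approx(direct.z)
        assert row["p"] == pytest.approx(direct.p)
        assert row["k"] == direct.k

    def test_excluding_driver_variant_reverts_toward_null(self, burden_setup):
        asn, geno = burden_setup
        ns = ["big", "null1", "null2"]
        with_big, _ = pct.burden_collapse(asn, geno, {"NS": ns})
        without_big, _ = pct.burden_collapse(asn, geno, {"NS": ns}, exclusions=["big"])
        assert abs(without_big["mean_percentile"].iloc[0] - 50) < abs(
            with_big["mean_percentile"].iloc[0] - 50
        )

    def test_identical_groups_compare_null(self, burden_setup):
        asn, geno = burden_setup
        _, pairwise = pct.burden_collapse(
            asn, geno, {"a": ["null1"], "b": ["null1"]}
        )
        assert pairwise["p"].iloc[0] > 0.99

    def test_unknown_exclusion_rejected(self, burden_setup):
        asn, geno = burden_setup
        with pytest.raises(KeyError):
            pct.burden_collapse(asn, geno, {"NS": ["big"]}, exclusions=["ghost"])


class TestVarianceExplained:
    def test_trait_equal_to_carrier_indicator(self):
        g = syn.simulate_genotypes(np.array([0.005]), 2000, seed=5)
        assert g.variants["n_hom_alt"].iloc[0] == 0  # all carriers heterozygous
        cohort = tiny_cohort(np.zeros(2000))
        cohort["apoa1"] = (g.matrix[:, 0] > 0).astype(float)
        out = pct.variance_explained(cohort, "apoa1", g, {"v": ["v1"]})
        assert out["r_squared"].iloc[0] == pytest.approx(1.0)

    def test_null_r2_scales_like_k_over_n(self):
        n, k = 2000, 10
        g = syn.simulate_genotypes(np.full(k, 0.2), n, seed=6)
        rng = np.random.default_rng(7)
        cohort = tiny_cohort(rng.normal(140, 30, size=n))
        out = pct.variance_explained(
            cohort, "apoa1", g, {"all": g.variant_ids}
        )
        r2 = out["r_squared"].iloc[0]
        assert 0.0 < r2 < 3 * k / n

    def test_recovers_planted_common_variant_contribution(self):
        # two common variants calibrated to a joint R^2 of 0.004 on apoA-I
        sigma2 = (0.20 * 140) ** 2
        f1, f2 = 0.035, 0.16
        b1 = np.sqrt(0.002 * sigma2 / (2 * f1 * (1 - f1)))
        b2 = np.sqrt(0.002 * sigma2 / (2 * f2 * (1 - f2)))
        specs = (
            VariantSpec("c1", "promoter", f1, apoa1_effect=float(b1)),
            VariantSpec("c2", "promoter", f2, apoa1_effect=float(b2)),
        )
        cfg = GeneratorConfig(
            n_individuals=45_000, seed=91, variant_specs=specs, followup_years=0.0
        )
        cohort, geno = syn.generate_cohort(cfg)
        out = pct.variance_explained(
            cohort, "apoa1", geno, {"common": ["c1", "c2"]}
        )
        assert 0.002 <= out["r_squared"].iloc[0] <= 0.006

    def test_nested_fit_dominates_components(self, discovery_study):
        cohort, geno = discovery_study
        poly, _ = geno.drop_monomorphic()
        ns = [v for v in poly.variant_ids if poly.variants.loc[v, "functional_class"] == "NS"]
        common = [v for v in poly.variant_ids if poly.variants.loc[v, "maf"] > 0.01]
        groups = {"ns": ns, "common": common, "both": ns + common}
        out = pct.variance_explained(cohort, "apoa1", poly, groups).set_index("group")
        assert out.loc["both", "r_squared"] >= out.loc["ns", "r_squared"] - 1e-12
        assert out.loc["both", "r_squared"] >= out.loc["common", "r_squared"] - 1e-12


class TestDifferenceRecord:
    def test_absolute_and_relative_deltas(self):
        rec = pct.difference_record(156.0, 117.0, carrier_median_percentile=5.0)
        assert rec["delta_abs"] == pytest.approx(39.0)
        assert rec["delta_rel"] == pytest.approx(45.0)

    def test_signs_agree_for_monotone_effects(self, discovery_study):
        cohort, geno = discovery_study
        asn = pct.assign_percentiles(cohort, "apoa1")
        carriers = geno.carriers("LOF_severe")
        noncar = np.setdiff1d(np.arange(len(cohort)), carriers)
        rec = pct.difference_record(
            float(cohort["apoa1"].iloc[noncar].median()),
            float(cohort["apoa1"].iloc[carriers].median()),
            float(np.median(asn["percentile"].to_numpy()[carriers])),
        )
        assert np.sign(rec["delta_abs"]) == np.sign(rec["delta_rel"]) == 1.0
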