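"""Synthetic-cohort generator: HWE structure, marginals, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lipidgrs as lg
from lipidgrs import reference
from lipidgrs._validation import ValidationError
from lipidgrs.cohort import CohortProfile, TraitEffects


def _one_snp_panel(maf):
    return pd.DataFrame(
        {"rsid": ["rsX"], "maf_combined": [maf], "maf_rural": [maf], "maf_urban": [maf]}
    )


class TestSimulateGenotypes:
    def test_zero_maf_gives_all_reference_homozygotes(self):
        G = lg.simulate_genotypes(_one_snp_panel(0.0), 500, ["rural"] * 500, seed=0)
        assert (G["rsX"] == 0).all()

    def test_mean_dosage_at_half_maf(self):
        n = 100_000
        G = lg.simulate_genotypes(_one_snp_panel(0.5), n, ["urban"] * n, seed=1)
        assert G["rsX"].mean() == pytest.approx(1.0, abs=0.01)

    def test_genotype_class_frequencies_match_hwe_closed_form(self):
        # p = 0.34: (1-p)^2, 2p(1-p), p^2 = 0.4356, 0.4488, 0.1156
        n = 100_000
        G = lg.simulate_genotypes(_one_snp_panel(0.34), n, ["rural"] * n, seed=2)
        freqs = G["rsX"].value_counts(normalize=True)
        assert freqs[0.0] == pytest.approx(0.4356, abs=0.005)
        assert freqs[1.0] == pytest.approx(0.4488, abs=0.005)
        assert freqs[2.0] == pytest.approx(0.1156, abs=0.005)

    def test_site_specific_mafs_are_used(self, panel):
        n = 40_000
        sites = np.array(["rural"] * (n // 2) + ["urban"] * (n // 2))
        G = lg.simulate_genotypes(panel, n, sites, seed=3)
        rural_maf = G.loc[sites == "rural", "rs2293889"].mean() / 2
        urban_maf = G.loc[sites == "urban", "rs2293889"].mean() / 2
        assert rural_maf == pytest.approx(0.31, abs=0.01)
        assert urban_maf == pytest.approx(0.36, abs=0.01)

    def test_invalid_maf_and_site_rejected(self):
        with pytest.raises(ValidationError):
            lg.simulate_genotypes(_one_snp_panel(0.6), 10, ["rural"] * 10)
        with pytest.raises(ValidationError):
            lg.simulate_genotypes(_one_snp_panel(0.2), 10, ["mars"] * 10)

    def test_simulated_variants_pass_hwe_at_nominal_rate(self):
        # HWE holds by construction: rejections at alpha should occur at ~alpha
        alpha, reps, n = 0.05, 400, 500
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(reps):
            d = rng.binomial(2, 0.25, size=n)
            res = lg.hwe_test(lg.GenotypeCounts.from_dosages(d), method="chisq")
            rejections += res.p < alpha
        assert rejections / reps == pytest.approx(alpha, abs=0.03)


class TestSimulateCovariates:
    def test_marginals_reproduced(self):
        profile = CohortProfile.reference()
        C = lg.simulate_covariates(profile, 10_000, seed=4)
        assert (C["site"] == "rural").mean() == pytest.approx(0.4237, abs=0.015)
        assert (C["gender"] == "male").mean() == pytest.approx(0.4525, abs=0.015)
        assert C["physical_activity"].isin([0, 1, 2, 3]).all()

    def test_age_mean_recovered(self):
        C = lg.simulate_covariates(CohortProfile.reference(), 50_000, seed=5)
        assert C["age"].mean() == pytest.approx(47.07, abs=0.2)

    def test_all_male_profile(self):
        profile = CohortProfile.reference()
        gs = {("male", "urban"): 0.6, ("male", "rural"): 0.4}
        profile = CohortProfile(profile.continuous, gs, profile.physical_activity, profile.binary)
        C = lg.simulate_covariates(profile, 200, seed=6)
        assert (C["gender"] == "male").all()

    def test_bad_proportions_rejected(self):
        profile = CohortProfile.reference()
        with pytest.raises(ValidationError):
            CohortProfile(profile.continuous, {("male", "urban"): 0.7}, profile.physical_activity, profile.binary)


class TestSimulatePhenotypes:
    def test_tg_geometric_mean_under_null_effects(self, panel):
        n = 100_000
        profile = CohortProfile.reference()
        C = lg.simulate_covariates(profile, n, seed=8)
        G = lg.simulate_genotypes(panel, n, C["site"].to_numpy(), seed=8)
        spec = {
            "TC": TraitEffects("TC", "normal", 183.68, 40.35),
            "HDL": TraitEffects("HDL", "normal", 46.97, 12.26),
            "TG": TraitEffects("TG", "log", 125.96, 1.60),
        }
        ct = lg.simulate_phenotypes(G, C, spec, seed=8)
        gm = np.exp(np.log(ct["TG"]).mean())
        assert gm == pytest.approx(125.96, abs=1.0)
        gsd = np.exp(np.log(ct["TG"]).std(ddof=1))
        assert gsd == pytest.approx(1.60, abs=0.02)

    def test_zero_noise_single_snp_is_collinear_with_dosage(self, panel):
        n = 500
        C = lg.simulate_covariates(CohortProfile.reference(), n, seed=9)
        G = lg.simulate_genotypes(panel, n, C["site"].to_numpy(), seed=9)
        spec = {
            "TC": TraitEffects("TC", "normal", 183.68, 40.35, {"rs2293889": 0.3}, residual_sd=1e-12),
            "HDL": TraitEffects("HDL", "normal", 46.97, 12.26, residual_sd=1.0),
            "TG": TraitEffects("TG", "log", 125.96, 1.60, residual_sd=1.0),
        }
        ct = lg.simulate_phenotypes(G, C, spec, seed=9)
        r = np.corrcoef(ct["TC"], G["rs2293889"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_derived_lipids(self, study_cohort):
        _, ct, _ = study_cohort
        assert np.allclose(ct["VLDL"], ct["TG"] / 5.0)
        ok = ct["LDL"].notna()
        assert ok.mean() > 0.95
        assert np.allclose(ct.loc[ok, "TC"], ct.loc[ok, "LDL"] + ct.loc[ok, "HDL"] + ct.loc[ok, "VLDL"])
        assert (ct.loc[ok, "LDL"] > 0).all()

    def test_missing_covariate_column_rejected(self, panel):
        C = lg.simulate_covariates(CohortProfile.reference(), 50, seed=1)
        G = lg.simulate_genotypes(panel, 50, C["site"].to_numpy(), seed=1)
        spec = {
            t: TraitEffects(t, "normal", 100.0, 10.0, covariate_effects={"shoe_size": 0.1})
            for t in ("TC", "HDL", "TG")
        }
        with pytest.raises(ValidationError):
            lg.simulate_phenotypes(G, C, spec, seed=1)


class TestApplyMissingness:
    def test_full_call_rate_is_identity(self, study_cohort):
        G, _, _ = study_cohort
        out = lg.apply_missingness(G, 1.0, seed=0)
        pd.testing.assert_frame_equal(out, G)

    def test_observed_call_rate_matches_target(self, panel):
        n = 100_000
        G = lg.simulate_genotypes(panel.head(10), n, ["rural"] * n, seed=11)
        out = lg.apply_missingness(G, 0.95, seed=11)
        per_snp = out.notna().mean(axis=0)
        assert np.all(np.abs(per_snp - 0.95) < 0.005)

    def test_masked_count_is_binomial(self):
        G = pd.DataFrame(np.zeros((10, 12)), columns=[f"rs{i}" for i in range(12)])
        masked = [lg.apply_missingness(G, 0.5, seed=s).isna().to_numpy().sum() for s in range(200)]
        m = 10 * 12
        # Binomial(120, 0.5): mean 60, sd ~5.5; sample mean of 200 draws within 4 se
        assert np.mean(masked) == pytest.approx(m * 0.5, abs=4 * np.sqrt(m * 0.25 / 200))

    def test_invalid_call_rate_rejected(self, study_cohort):
        G, _, _ = study_cohort
        with pytest.raises(ValidationError):
            lg.apply_missingness(G, 0.0)


class TestDeterminism:
    def test_same_seed_reproduces_everything_bitwise(self):
        a = lg.simulate_cohort(n=300, seed=42, call_rate=0.9)
        b = lg.simulate_cohort(n=300, seed=42, call_rate=0.9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_different_seed_differs(self):
        a = lg.simulate_cohort(n=300, seed=1)
        b = lg.simulate_cohort(n=300, seed=2)
        assert not a[0].equals(b[0])


def test_null_effect_pvalues_are_uniform():
    """With zero genetic effects, per-variant association p-values ~ U(0,1)."""
    rng = np.random.default_rng(99)
    n, reps = 400, 600
    pvals = []
    for _ in range(reps):
        d = rng.binomial(2, 0.3, size=n).astype(float)
        y = rng.normal(size=n)
        res = lg.fit_additive_model(y, d, None, None)
        pvals.append(res.p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
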