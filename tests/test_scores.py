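"""Risk scores: selection, orientation, score arithmetic, association."""

import numpy as np
import pandas as pd
import pytest

import lipidgrs as lg
from lipidgrs import reference
from lipidgrs._validation import OrientationError, ValidationError
from lipidgrs.scores import ScoreDefinition, build_score_definition

EXPECTED_SETS = {
    "TG": ["rs174546", "rs17482753", "rs2293889", "rs4148005", "rs4420638"],
    "TC": ["rs2293889", "rs4147536"],
    "HDL": ["rs174546", "rs17482753", "rs4148005", "rs4420638", "rs7832643"],
    "LDL": ["rs2293889", "rs4147536", "rs4420638", "rs660240"],
    "VLDL": ["rs174546", "rs17482753", "rs2293889", "rs4148005", "rs4420638"],
}


class TestSelection:
    @pytest.mark.parametrize("trait", list(EXPECTED_SETS))
    def test_published_pvalues_reproduce_reported_sets(self, published, panel, trait):
        sel = lg.select_validated_variants(published, trait, 0.05, panel["rsid"])
        assert sel == EXPECTED_SETS[trait]

    def test_union_covers_eight_loci(self, published, panel):
        union = set()
        for trait in EXPECTED_SETS:
            union |= set(lg.select_validated_variants(published, trait, 0.05, panel["rsid"]))
        assert len(union) == 8

    def test_tiny_alpha_empty(self, published):
        assert lg.select_validated_variants(published, "TG", 1e-12) == []

    def test_missing_model_rejected(self, published):
        only1 = published[published["model"] == 1]
        with pytest.raises(ValidationError):
            lg.select_validated_variants(only1, "TG", 0.05)


class TestOrientation:
    def test_major_risk_flags_reproduced(self, published, panel):
        """Variants flagged major-risk orient to the major allele in their sets."""
        for trait, sel in EXPECTED_SETS.items():
            oriented = lg.orient_risk_alleles(published, trait, sel)
            for row in oriented.itertuples():
                expected = "major" if row.rsid in reference.RISK_MAJOR_VARIANTS else "minor"
                assert row.counted_allele == expected, (trait, row.rsid)

    def test_hdl_lowering_minor_allele_counted(self, published):
        oriented = lg.orient_risk_alleles(published, "HDL", ["rs174546"])
        assert oriented.loc[0, "counted_allele"] == "minor"
        assert oriented.loc[0, "weight"] == pytest.approx(0.10)

    def test_sign_convention_flip_symmetry(self, published):
        flipped = published.copy()
        flipped["beta"] = -flipped["beta"]
        a = lg.orient_risk_alleles(published, "TG", EXPECTED_SETS["TG"])
        b = lg.orient_risk_alleles(flipped, "TG", EXPECTED_SETS["TG"])
        assert (a["counted_allele"] != b["counted_allele"]).all()
        assert np.allclose(a["weight"], b["weight"])

    def test_zero_effect_rejected(self, published):
        zeroed = published.copy()
        zeroed.loc[zeroed["rsid"] == "rs2293889", "beta"] = 0.0
        with pytest.raises(OrientationError):
            lg.orient_risk_alleles(zeroed, "TG", ["rs2293889"])


def _definition(weights=(0.11, 0.21, 0.08, 0.11, 0.10), weighting="weighted"):
    return ScoreDefinition(
        "TG",
        ("a", "b", "c", "d", "e"),
        (True, True, True, True, True),
        weights,
        weighting=weighting,
    )


class TestScoreArithmetic:
    def test_weighted_sum_example(self):
        G = pd.DataFrame([[1.0, 0.0, 2.0, 1.0, 0.0]], columns=list("abcde"))
        w = lg.compute_wgrs(G, _definition())
        assert w.iloc[0] == pytest.approx(0.11 + 0.16 + 0.11)

    def test_all_homozygous_risk(self):
        G = pd.DataFrame(np.full((3, 5), 2.0), columns=list("abcde"))
        assert (lg.compute_ugrs(G, _definition()) == 10.0).all()

    def test_zero_dosages(self):
        G = pd.DataFrame(np.zeros((2, 5)), columns=list("abcde"))
        assert (lg.compute_wgrs(G, _definition()) == 0.0).all()

    def test_ugrs_equals_wgrs_under_unit_weights(self, study_cohort, study_associations, panel):
        G, _, _ = study_cohort
        d = build_score_definition(study_associations, "TG", panel_order=list(panel["rsid"]))
        unit = ScoreDefinition(d.trait, d.rsids, d.counted_is_minor, (1.0,) * len(d.rsids))
        assert np.allclose(lg.compute_ugrs(G, d), lg.compute_wgrs(G, unit), equal_nan=True)

    def test_doubling_weights_doubles_scores_and_halves_fitted_beta(self, study_cohort, study_associations, panel):
        G, ct, _ = study_cohort
        d = build_score_definition(study_associations, "TG", panel_order=list(panel["rsid"]))
        double = ScoreDefinition(d.trait, d.rsids, d.counted_is_minor, tuple(2 * w for w in d.weights))
        s1, s2 = lg.compute_wgrs(G, d), lg.compute_wgrs(G, double)
        assert np.allclose(s2, 2 * s1, equal_nan=True)
        from lipidgrs.association import prepare_traits

        z, _ = prepare_traits(ct, ("TG",))
        r1 = lg.grs_association(s1, ct, z["TG"], "TG")
        r2 = lg.grs_association(s2, ct, z["TG"], "TG")
        assert r2.beta == pytest.approx(r1.beta / 2, rel=1e-9)
        assert r2.p == pytest.approx(r1.p, rel=1e-9)

    def test_missing_genotypes_imputed_at_expected_dosage(self):
        G = pd.DataFrame({"a": [0.0, 2.0, np.nan, np.nan], "b": [1.0, 1.0, 1.0, np.nan]})
        d = ScoreDefinition("TG", ("a", "b"), (True, True), (1.0, 1.0))
        s = lg.compute_ugrs(G, d)
        assert s.iloc[2] == pytest.approx(1.0 + 1.0)  # mean(a)=1, observed b=1
        assert np.isnan(s.iloc[3])  # all genotypes missing: undefined

    def test_person_missing_all_genotypes_flagged(self):
        G = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, np.nan]})
        d = ScoreDefinition("TG", ("a", "b"), (True, True), (1.0, 1.0))
        assert np.isnan(lg.compute_ugrs(G, d).iloc[1])

    def test_count_normalized_rescale(self):
        G = pd.DataFrame([[2.0, 2.0]], columns=["a", "b"])
        d = ScoreDefinition("TG", ("a", "b"), (True, True), (0.1, 0.3), rescale="count_normalized")
        # weights scaled by i/sum(w) = 2/0.4 -> (0.5, 1.5); score = 4
        assert lg.compute_wgrs(G, d).iloc[0] == pytest.approx(4.0)


class TestScoreAssociation:
    def test_wgrs_tg_positive_and_significant(self, study_cohort, study_associations, panel):
        G, ct, _ = study_cohort
        from lipidgrs.association import prepare_traits

        d = build_score_definition(study_associations, "TG", panel_order=list(panel["rsid"]))
        s = lg.compute_wgrs(G, d)
        z, _ = prepare_traits(ct, ("TG",))
        res = lg.grs_association(s, ct, z["TG"], "TG")
        assert res.beta > 0
        assert res.p < 0.001

    def test_hdl_score_negative_beta(self, study_cohort, study_associations, panel):
        """Counting HDL-lowering alleles with positive weights gives beta < 0."""
        G, ct, _ = study_cohort
        from lipidgrs.association import prepare_traits

        d = build_score_definition(study_associations, "HDL", panel_order=list(panel["rsid"]))
        assert all(w > 0 for w in d.weights)
        s = lg.compute_wgrs(G, d)
        z, _ = prepare_traits(ct, ("HDL",))
        res = lg.grs_association(s, ct, z["HDL"], "HDL")
        assert res.beta < 0

    def test_null_score_type_i(self):
        rng = np.random.default_rng(13)
        n, reps = 800, 400
        rejections = 0
        for _ in range(reps):
            s = pd.Series(rng.normal(size=n))
            y = rng.normal(size=n)
            rejections += lg.grs_association(s, None, y, "TG", spec=None).p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.03)

    def test_invariant_to_upstream_allele_coding(self, study_cohort, study_associations, panel):
        """Flipping a variant's minor coding upstream leaves the score fit unchanged."""
        G, ct, _ = study_cohort
        from lipidgrs.association import prepare_traits

        d = build_score_definition(study_associations, "TG", panel_order=list(panel["rsid"]))
        # flip one variant's dosage and its orientation flag
        rsid = d.rsids[0]
        G2 = G.copy()
        G2[rsid] = 2.0 - G2[rsid]
        flags = list(d.counted_is_minor)
        flags[0] = not flags[0]
        d2 = ScoreDefinition(d.trait, d.rsids, tuple(flags), d.weights)
        z, _ = prepare_traits(ct, ("TG",))
        r1 = lg.grs_association(lg.compute_wgrs(G, d), ct, z["TG"], "TG")
        r2 = lg.grs_association(lg.compute_wgrs(G2, d2), ct, z["TG"], "TG")
        assert r1.beta == pytest.approx(r2.beta, rel=1e-9)

    def test_aggregation_beats_single_variants_most_of_the_time(self):
        """|t| of the combined score >= max single-variant |t| (majority prop.)."""
        rng = np.random.default_rng(17)
        wins = 0
        reps = 100
        betas = np.array([0.11, 0.21, 0.08, 0.11, 0.10])
        mafs = np.array([0.14, 0.08, 0.34, 0.26, 0.11])
        n = 800
        for _ in range(reps):
            D = np.column_stack([rng.binomial(2, m, n) for m in mafs]).astype(float)
            var_g = float(np.sum(betas**2 * 2 * mafs * (1 - mafs)))
            y = (D - D.mean(0)) @ betas + rng.normal(0, np.sqrt(1 - var_g), n)
            s = pd.Series(D @ betas)
            t_score = abs(lg.grs_association(s, None, y, "TG", spec=None).beta
                          / lg.grs_association(s, None, y, "TG", spec=None).se)
            t_single = max(
                abs(r.beta / r.se)
                for r in (lg.fit_additive_model(y, D[:, j], None, None) for j in range(5))
            )
            wins += t_score >= t_single
        assert wins / reps > 0.5
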