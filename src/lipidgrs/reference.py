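"""Published summary statistics of the North Indian rural-urban lipid cohort.

A cohort of 2,117 adults recruited around Delhi (urban) and Ballabgarh, Haryana
(rural) was genotyped at 12 established lipid-associated GWAS variants and
phenotyped for a fasting lipid panel.  This module embeds the study's printed
summary tables:

* the candidate-variant panel with site-specific minor-allele frequencies;
* cohort covariate marginals (age, BMI, fat intake, physical activity,
  gender x site counts, binary risk factors) and lipid trait summaries;
* the per-variant association estimates (beta, SE, p) for each of the five
  lipid traits under the two covariate-adjustment models, plus the published
  GRS/wGRS rows.

These printed values are inputs in their own right: the synthetic-cohort
generator is calibrated to them, and the risk-score stage consumes the
published effect estimates exactly as the study's own score construction did.

Notes on encoding: p-values printed as "<0.001" are stored as 5e-4 (only the
0.05 significance threshold is consumed downstream).  Three variants are
flagged in the source table as having the *major* allele as the risk allele;
their printed betas are coded on the major allele, recorded in the
``coded_allele`` column.
"""

from __future__ import annotations

import pandas as pd

from .transforms import TraitSummary

__all__ = [
    "N_PARTICIPANTS",
    "TRAITS",
    "LOG_TRAITS",
    "RISK_MAJOR_VARIANTS",
    "variant_panel",
    "published_associations",
    "published_grs_rows",
    "trait_summaries",
    "COHORT_CONTINUOUS",
    "GENDER_SITE_COUNTS",
    "PHYSICAL_ACTIVITY_PROPS",
    "BINARY_PROPS",
]

#: Study sample size after genotyping QC.
N_PARTICIPANTS = 2117

#: Lipid traits analysed, in report order.
TRAITS = ("TG", "TC", "HDL", "LDL", "VLDL")

#: Traits analysed on the natural-log scale (right-skewed).
LOG_TRAITS = ("TG", "VLDL")

#: Variants whose risk allele is the major allele ("$" flag in the source
#: table); their published betas are coded on the major allele.
RISK_MAJOR_VARIANTS = frozenset({"rs17482753", "rs4147536", "rs660240"})

# rsid, locus, chrom:pos (GRCh38, informational), ref, alt, minor allele,
# MAF combined / rural / urban
_PANEL = [
    ("rs10773003", "SBNO1", "12:123290580", "G", "A", "A", 0.11, 0.10, 0.12),
    ("rs174546", "FADS1", "11:61802358", "C", "T", "T", 0.14, 0.12, 0.15),
    ("rs17482753", "LPL", "8:19975135", "G", "T", "T", 0.08, 0.08, 0.07),
    ("rs1800961", "HNF4A", "20:44413724", "C", "T", "T", 0.02, 0.02, 0.02),
    ("rs2293889", "TRPS1", "8:115586972", "G", "T", "T", 0.34, 0.31, 0.36),
    ("rs2814944", "C6orf106", "6:34585020", "G", "A", "A", 0.10, 0.11, 0.10),
    ("rs4147536", "ADH1B", "4:99317955", "G", "T", "T", 0.22, 0.20, 0.24),
    ("rs4148005", "ABCA8", "17:68886325", "A", "C", "C", 0.26, 0.23, 0.28),
    ("rs4420638", "APOC1", "19:44919689", "A", "G", "G", 0.11, 0.10, 0.11),
    ("rs660240", "CELSR2", "1:109275216", "G", "A", "A", 0.24, 0.21, 0.21),
    ("rs737337", "DOCK6", "19:11236817", "T", "C", "C", 0.13, 0.13, 0.13),
    ("rs7832643", "PLEC", "8:143948489", "G", "T", "T", 0.30, 0.27, 0.32),
]

_PANEL_COLUMNS = [
    "rsid",
    "locus",
    "chrom_pos",
    "ref",
    "alt",
    "minor_allele",
    "maf_combined",
    "maf_rural",
    "maf_urban",
]


def variant_panel() -> pd.DataFrame:
    """The 12-variant candidate panel with site-specific MAFs."""
    df = pd.DataFrame(_PANEL, columns=_PANEL_COLUMNS)
    df["risk_is_major"] = df["rsid"].isin(RISK_MAJOR_VARIANTS)
    return df


# Published per-variant estimates.  Each entry: rsid -> model -> trait order
# (TG, TC, HDL, LDL, VLDL) of (beta, se, p).  "<0.001" stored as 5e-4.
_LT = 5e-4
_ASSOC = {
    "rs10773003": {
        1: [(-0.04, 0.05, 0.383), (-0.02, 0.05, 0.721), (0.00, 0.05, 0.990), (-0.02, 0.05, 0.742), (-0.04, 0.05, 0.383)],
        2: [(-0.05, 0.05, 0.312), (0.00, 0.05, 0.921), (0.01, 0.05, 0.796), (-0.01, 0.05, 0.909), (-0.05, 0.05, 0.312)],
    },
    "rs174546": {
        1: [(0.13, 0.04, 0.004), (-0.03, 0.04, 0.471), (-0.11, 0.04, 0.010), (-0.06, 0.04, 0.181), (0.13, 0.04, 0.004)],
        2: [(0.11, 0.04, 0.014), (-0.06, 0.05, 0.191), (-0.10, 0.04, 0.025), (-0.09, 0.04, 0.036), (0.11, 0.04, 0.014)],
    },
    "rs17482753": {
        1: [(0.19, 0.06, 0.001), (0.05, 0.06, 0.418), (-0.13, 0.06, 0.018), (0.02, 0.06, 0.756), (0.19, 0.06, 0.001)],
        2: [(0.21, 0.06, _LT), (0.06, 0.06, 0.332), (-0.14, 0.06, 0.018), (0.03, 0.06, 0.662), (0.21, 0.06, _LT)],
    },
    "rs1800961": {
        1: [(-0.05, 0.11, 0.668), (-0.23, 0.11, 0.038), (-0.23, 0.11, 0.040), (-0.15, 0.11, 0.176), (-0.05, 0.11, 0.668)],
        2: [(-0.06, 0.11, 0.585), (-0.21, 0.12, 0.066), (-0.22, 0.11, 0.055), (-0.13, 0.12, 0.260), (-0.06, 0.11, 0.585)],
    },
    "rs2293889": {
        1: [(0.08, 0.03, 0.023), (0.08, 0.03, 0.013), (-0.06, 0.03, 0.094), (0.09, 0.03, 0.005), (0.08, 0.03, 0.023)],
        2: [(0.08, 0.03, 0.015), (0.10, 0.03, 0.004), (-0.06, 0.03, 0.062), (0.11, 0.03, 0.001), (0.08, 0.03, 0.015)],
    },
    "rs2814944": {
        1: [(0.05, 0.05, 0.370), (-0.03, 0.05, 0.583), (0.07, 0.05, 0.152), (-0.02, 0.05, 0.633), (0.05, 0.05, 0.370)],
        2: [(0.06, 0.05, 0.233), (0.00, 0.05, 0.937), (0.04, 0.05, 0.440), (-0.06, 0.05, 0.235), (0.06, 0.05, 0.233)],
    },
    "rs4147536": {
        1: [(0.04, 0.04, 0.259), (0.10, 0.04, 0.004), (0.06, 0.04, 0.092), (0.10, 0.04, 0.007), (0.04, 0.04, 0.259)],
        2: [(0.05, 0.04, 0.187), (0.12, 0.04, 0.001), (0.09, 0.04, 0.014), (0.10, 0.04, 0.006), (0.05, 0.04, 0.187)],
    },
    "rs4148005": {
        1: [(0.09, 0.03, 0.010), (-0.04, 0.03, 0.299), (-0.13, 0.03, _LT), (-0.05, 0.03, 0.187), (0.09, 0.03, 0.010)],
        2: [(0.11, 0.04, 0.001), (-0.01, 0.04, 0.814), (-0.13, 0.03, _LT), (-0.02, 0.04, 0.482), (0.11, 0.04, 0.001)],
    },
    "rs4420638": {
        1: [(0.11, 0.05, 0.027), (0.08, 0.05, 0.123), (-0.17, 0.05, _LT), (0.13, 0.05, 0.009), (0.11, 0.05, 0.027)],
        2: [(0.10, 0.05, 0.044), (0.07, 0.05, 0.191), (-0.15, 0.05, 0.003), (0.11, 0.05, 0.028), (0.10, 0.05, 0.044)],
    },
    "rs660240": {
        1: [(-0.01, 0.04, 0.734), (0.09, 0.04, 0.013), (-0.01, 0.04, 0.734), (0.12, 0.04, 0.001), (-0.01, 0.04, 0.734)],
        2: [(0.00, 0.04, 0.933), (0.07, 0.04, 0.059), (-0.01, 0.04, 0.830), (0.08, 0.04, 0.020), (0.00, 0.04, 0.933)],
    },
    "rs737337": {
        1: [(0.05, 0.04, 0.300), (-0.04, 0.04, 0.417), (-0.08, 0.04, 0.068), (-0.04, 0.04, 0.410), (0.05, 0.04, 0.300)],
        2: [(0.01, 0.05, 0.767), (-0.03, 0.05, 0.533), (-0.06, 0.05, 0.188), (-0.02, 0.05, 0.716), (0.01, 0.05, 0.767)],
    },
    "rs7832643": {
        1: [(-0.02, 0.03, 0.600), (-0.04, 0.03, 0.174), (-0.11, 0.03, 0.001), (-0.01, 0.03, 0.761), (-0.02, 0.03, 0.600)],
        2: [(-0.02, 0.03, 0.507), (-0.04, 0.03, 0.279), (-0.09, 0.03, 0.004), (-0.01, 0.03, 0.879), (-0.02, 0.03, 0.507)],
    },
}

# Published combined-score rows (model-1 adjusted), trait order as TRAITS.
_GRS_ROWS = {
    "GRS": [(0.10, 0.02, _LT), (0.09, 0.02, _LT), (-0.11, 0.01, _LT), (0.11, 0.02, _LT), (0.10, 0.02, _LT)],
    "wGRS": [(0.95, 0.16, _LT), (1.01, 0.23, _LT), (-0.87, 0.14, _LT), (1.03, 0.19, _LT), (0.95, 0.16, _LT)],
}


def published_associations() -> pd.DataFrame:
    """Long-format published per-variant estimates.

    Columns: rsid, trait, model, beta, se, p, coded_allele.  Betas of the
    three major-risk-allele variants are coded on the major allele; all
    others on the minor allele.
    """
    rows = []
    for rsid, models in _ASSOC.items():
        coded = "major" if rsid in RISK_MAJOR_VARIANTS else "minor"
        for model, cells in models.items():
            for trait, (beta, se, p) in zip(TRAITS, cells):
                rows.append((rsid, trait, model, beta, se, p, coded))
    return pd.DataFrame(
        rows, columns=["rsid", "trait", "model", "beta", "se", "p", "coded_allele"]
    )


def published_grs_rows() -> pd.DataFrame:
    """Published unweighted/weighted risk-score association rows (Model 1)."""
    rows = []
    for score, cells in _GRS_ROWS.items():
        for trait, (beta, se, p) in zip(TRAITS, cells):
            rows.append((score, trait, 1, beta, se, p))
    return pd.DataFrame(rows, columns=["score", "trait", "model", "beta", "se", "p"])


def trait_summaries() -> dict[str, TraitSummary]:
    """Published lipid summaries: mean (SD) mg/dL, or geometric mean (GSD)."""
    return {
        "TC": TraitSummary("TC", "normal", 183.68, 40.35),
        "TG": TraitSummary("TG", "log", 125.96, 1.60),
        "HDL": TraitSummary("HDL", "normal", 46.97, 12.26),
        "LDL": TraitSummary("LDL", "normal", 108.10, 33.13),
        "VLDL": TraitSummary("VLDL", "log", 25.19, 1.60),
    }


#: Continuous covariate marginals: mean, SD, truncation bounds.
COHORT_CONTINUOUS = {
    "age": (47.07, 12.99, 18.0, 95.0),
    "bmi": (24.91, 5.25, 12.0, 55.0),
    "fat_intake": (31.09, 5.05, 5.0, 70.0),
}

#: Gender x site cell counts (sum = 2,117); 42.37% rural, 45.25% male.
GENDER_SITE_COUNTS = {
    ("male", "urban"): 565,
    ("female", "urban"): 655,
    ("male", "rural"): 393,
    ("female", "rural"): 504,
}

#: Physical-activity category proportions (inactive/low/moderate/high).
PHYSICAL_ACTIVITY_PROPS = (0.1150, 0.5273, 0.2526, 0.1050)

#: Binary covariate prevalences.
BINARY_PROPS = {
    "alcohol": 0.2390,
    "smoking": 0.2352,
    "diabetes": 0.0798,
    "hypertension": 0.1890,
}
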