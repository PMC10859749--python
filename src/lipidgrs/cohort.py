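"""Synthetic cohort generator.

Simulates genotype/phenotype/covariate tables with the statistical structure
the downstream analysis assumes, so that every stage — QC, transformation,
association, risk scores, interactions, power — is testable without access to
the controlled study data.

The generative model, per person:

* genotypes: minor-allele dosage at each panel SNP drawn Binomial(2, MAF) with
  the site-specific MAF (rural/urban), independently across SNPs — Hardy-
  Weinberg equilibrium and no linkage disequilibrium hold by construction
  (the panel's 12 SNPs sit on 9 chromosomes and are analysed independently);
* covariates: gender x site drawn from the cohort cross-tab, continuous
  covariates from truncated normals, physical activity and binary risk
  factors from their stated proportions; covariates are mutually independent
  beyond the gender x site coupling (only marginals are available);
* phenotypes: a standardized latent trait per lipid,
  ``z = sum_j beta_j (d_j - mean d_j) + sum_k gamma_k c_k + eps``, with the
  residual SD chosen so Var(z) = 1; normal traits are rescaled to
  (mean, SD), log traits built as ``exp(ln GM + ln GSD * z)``;
* VLDL-C = TG/5 exactly, LDL-C by the Friedewald equation from the simulated
  TC/HDL/TG (NaN where TG >= 400 mg/dL or the derived value is non-positive);
* missingness: each genotype call independently dropped with probability
  ``1 - call_rate`` (the study reports >= 95% call rates).

Everything is driven by one integer seed through ``numpy.random.default_rng``;
a fixed seed fixes every output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from ._validation import ValidationError
from .transforms import friedewald_ldl, vldl_from_tg

__all__ = [
    "CohortProfile",
    "TraitEffects",
    "default_effect_spec",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotypes",
    "apply_missingness",
    "simulate_cohort",
]

#: Default cohort size, matching the study.
DEFAULT_N = reference.N_PARTICIPANTS

COVARIATE_COLUMNS = (
    "age",
    "gender",
    "site",
    "bmi",
    "fat_intake",
    "physical_activity",
    "alcohol",
    "smoking",
    "diabetes",
    "hypertension",
)


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CohortProfile:
    """Covariate marginals driving :func:`simulate_covariates`.

    ``continuous`` maps column -> (mean, sd, low, high); ``gender_site`` maps
    (gender, site) -> proportion; ``physical_activity`` holds the four
    category proportions; ``binary`` maps column -> prevalence.
    """

    continuous: dict
    gender_site: dict
    physical_activity: tuple
    binary: dict

    def __post_init__(self):
        for probs in (tuple(self.gender_site.values()), self.physical_activity, tuple(self.binary.values())):
            for p in probs:
                if not 0.0 <= p <= 1.0:
                    raise ValidationError("proportions must lie in [0, 1]")
        for name, total in (
            ("gender_site", sum(self.gender_site.values())),
            ("physical_activity", sum(self.physical_activity)),
        ):
            if abs(total - 1.0) > 1e-6:
                raise ValidationError(f"{name} proportions must sum to 1 (got {total:.6f})")

    @classmethod
    def reference(cls) -> "CohortProfile":
        """Profile calibrated to the published cohort marginals."""
        total = sum(reference.GENDER_SITE_COUNTS.values())
        gs = {k: v / total for k, v in reference.GENDER_SITE_COUNTS.items()}
        pa = np.asarray(reference.PHYSICAL_ACTIVITY_PROPS, dtype=float)
        pa = tuple(pa / pa.sum())
        return cls(dict(reference.COHORT_CONTINUOUS), gs, pa, dict(reference.BINARY_PROPS))


@dataclass(frozen=True)
class TraitEffects:
    """True generative effects for one trait on the standardized scale.

    ``snp_effects`` maps rsid -> per-minor-allele effect in trait-SD units;
    ``covariate_effects`` maps covariate column -> effect per SD of the
    (standardized) covariate.  ``residual_sd=None`` means "whatever makes the
    total standardized variance 1".  ``summary`` carries the target location
    and scale: (mean, SD) mg/dL for a normal trait, (GM, GSD) for a log one.
    """

    trait: str
    scale: str  # "normal" | "log"
    mean: float
    sd: float
    snp_effects: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    residual_sd: float | None = None

    def __post_init__(self):
        if self.residual_sd is not None and not self.residual_sd > 0:
            raise ValidationError("residual SD must be positive")


def default_effect_spec(model: int = 2) -> dict[str, TraitEffects]:
    """Generative effects calibrated to the published fully-adjusted estimates.

    TC, HDL and TG get per-allele effects equal to the published model-``model``
    betas (minor-allele coded); LDL and VLDL are derived downstream, so only
    the three measured traits are specified.  Covariate effects default to
    zero (the study publishes none).
    """
    assoc = reference.published_associations()
    assoc = assoc[assoc["model"] == model]
    summaries = reference.trait_summaries()
    spec = {}
    for trait in ("TC", "HDL", "TG"):
        sub = assoc[assoc["trait"] == trait]
        effects = {}
        for row in sub.itertuples():
            beta = row.beta
            # published betas of major-risk variants are major-allele coded;
            # the generator works on minor dosage, so flip the sign back
            if row.coded_allele == "major":
                beta = -beta
            effects[row.rsid] = beta
        s = summaries[trait]
        spec[trait] = TraitEffects(trait, s.scale, s.mean, s.sd, effects)
    return spec


def simulate_genotypes(panel: pd.DataFrame, n: int, sites, seed=0) -> pd.DataFrame:
    """Draw minor-allele dosages under HWE at site-specific MAFs.

    ``panel`` needs columns ``rsid`` plus ``maf_rural``/``maf_urban`` (or a
    single ``maf_combined`` used for every site when the per-site columns are
    absent).  ``sites`` is a length-``n`` sequence of "rural"/"urban".
    Returns a samples x rsids float DataFrame with values in {0, 1, 2}.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    sites = np.asarray(sites)
    if sites.shape[0] != n:
        raise ValidationError("site assignment must have length n")
    known = {"rural", "urban"}
    bad = set(np.unique(sites)) - known
    if bad:
        raise ValidationError(f"unknown site labels: {sorted(bad)}")
    rng = _rng(seed)
    per_site_cols = {"rural": "maf_rural", "urban": "maf_urban"}
    out = {}
    for row in panel.itertuples():
        dosage = np.empty(n, dtype=float)
        for site in known:
            col = per_site_cols[site]
            maf = getattr(row, col) if hasattr(row, col) else row.maf_combined
            if not 0.0 <= maf <= 0.5:
                raise ValidationError(f"{row.rsid} {site} MAF {maf} outside [0, 0.5]")
            mask = sites == site
            dosage[mask] = rng.binomial(2, maf, size=int(mask.sum()))
        out[row.rsid] = dosage
    idx = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    return pd.DataFrame(out, index=idx)


def _truncnorm_loc(target_mean, sd, low, high):
    """Location making the truncated normal's mean equal the stated marginal.

    Asymmetric truncation shifts the mean of a plain truncated normal; the
    location is re-centered by root finding so the simulated covariate
    reproduces the published mean."""
    from scipy.optimize import brentq

    def shifted(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return brentq(shifted, target_mean - 3 * sd, target_mean + 3 * sd)


def simulate_covariates(profile: CohortProfile, n: int, seed=0) -> pd.DataFrame:
    """Draw a covariate table from the profile's marginals."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = _rng(seed)
    cells = list(profile.gender_site.keys())
    probs = np.array([profile.gender_site[c] for c in cells])
    draw = rng.choice(len(cells), size=n, p=probs)
    gender = np.array([cells[i][0] for i in draw])
    site = np.array([cells[i][1] for i in draw])
    data = {"gender": gender, "site": site}
    for col, (mean, sd, low, high) in profile.continuous.items():
        loc = _truncnorm_loc(mean, sd, low, high)
        a, b = (low - loc) / sd, (high - loc) / sd
        data[col] = stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)
    pa = np.asarray(profile.physical_activity)
    data["physical_activity"] = rng.choice(4, size=n, p=pa)
    for col, prev in profile.binary.items():
        data[col] = (rng.random(n) < prev).astype(int)
    idx = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    df = pd.DataFrame(data, index=idx)
    return df[[c for c in COVARIATE_COLUMNS if c in df.columns]]


def _standardized_covariate(values: pd.Series) -> np.ndarray:
    x = values.to_numpy(dtype=float)
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_phenotypes(
    G: pd.DataFrame, covariates: pd.DataFrame, spec: dict[str, TraitEffects], seed=0
) -> pd.DataFrame:
    """Fill lipid columns from genotypes + covariates under additive effects.

    Requires ``spec`` entries for TC, HDL and TG; VLDL is TG/5 and LDL comes
    from the Friedewald equation.  Genotype NaNs (if phenotypes are simulated
    after missingness was applied) contribute their column mean.
    """
    for trait in ("TC", "HDL", "TG"):
        if trait not in spec:
            raise ValidationError(f"effect spec missing trait {trait}")
    rng = _rng(seed)
    n = len(G)
    cohort = covariates.copy()
    numeric_cov = {"gender": {"male": 0.0, "female": 1.0}, "site": {"urban": 0.0, "rural": 1.0}}

    for trait in ("TC", "HDL", "TG"):
        eff = spec[trait]
        z = np.zeros(n)
        explained = 0.0
        for rsid, beta in eff.snp_effects.items():
            if rsid not in G.columns:
                raise ValidationError(f"genotypes missing variant {rsid}")
            d = G[rsid].to_numpy(dtype=float)
            mu = np.nanmean(d)
            d = np.where(np.isnan(d), mu, d)
            z += beta * (d - mu)
            explained += beta**2 * float(np.var(d))
        for cov, gamma in eff.covariate_effects.items():
            if cov not in cohort.columns:
                raise ValidationError(f"covariate column {cov} missing")
            col = cohort[cov]
            if col.dtype == object:
                col = col.map(numeric_cov[cov])
            z += gamma * _standardized_covariate(col)
            explained += gamma**2
        if eff.residual_sd is not None:
            res_sd = eff.residual_sd
        else:
            if explained >= 1.0:
                raise ValidationError(
                    f"{trait}: explained standardized variance {explained:.3f} >= 1"
                )
            res_sd = float(np.sqrt(1.0 - explained))
        z += rng.normal(0.0, res_sd, size=n)
        if eff.scale == "log":
            cohort[trait] = np.exp(np.log(eff.mean) + np.log(eff.sd) * z)
        else:
            cohort[trait] = eff.mean + eff.sd * z
            cohort[trait] = cohort[trait].clip(lower=1.0)  # lipids are positive
    cohort["VLDL"] = vldl_from_tg(cohort["TG"].to_numpy())
    cohort["LDL"] = friedewald_ldl(
        cohort["TC"].to_numpy(), cohort["HDL"].to_numpy(), cohort["TG"].to_numpy()
    )
    order = [c for c in COVARIATE_COLUMNS if c in cohort.columns] + ["TC", "TG", "HDL", "LDL", "VLDL"]
    return cohort[order]


def apply_missingness(G: pd.DataFrame, call_rate: float, seed=0) -> pd.DataFrame:
    """Mask each genotype independently with probability ``1 - call_rate``."""
    if not 0.0 < call_rate <= 1.0:
        raise ValidationError("call_rate must be in (0, 1]")
    if call_rate == 1.0:
        return G.copy()
    rng = _rng(seed)
    mask = rng.random(G.shape) >= call_rate
    out = G.copy().astype(float)
    out.values[mask] = np.nan
    return out


def simulate_cohort(
    n: int = DEFAULT_N,
    seed: int = 0,
    panel: pd.DataFrame | None = None,
    profile: CohortProfile | None = None,
    spec: dict[str, TraitEffects] | None = None,
    call_rate: float = 1.0,
):
    """One-call generator: returns ``(genotypes, cohort_table, panel)``.

    Defaults reproduce the study conditions: the 12-variant panel at its
    published site-specific MAFs, published covariate marginals, published
    fully-adjusted per-allele effects, n = 2,117.
    """
    panel = reference.variant_panel() if panel is None else panel
    profile = CohortProfile.reference() if profile is None else profile
    spec = default_effect_spec() if spec is None else spec
    rng = np.random.default_rng(seed)
    covariates = simulate_covariates(profile, n, rng)
    G = simulate_genotypes(panel, n, covariates["site"].to_numpy(), rng)
    cohort = simulate_phenotypes(G, covariates, spec, rng)
    if call_rate < 1.0:
        G = apply_missingness(G, call_rate, rng)
    return G, cohort, panel
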