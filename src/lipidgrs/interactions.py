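"""Stratified association and SNP x modifier interaction screening.

Lipid levels differ strongly by gender and by rural/urban residence, so the
per-variant fits are re-run within those strata (with the stratifying
covariate dropped from the design), and effect modification is screened with
product terms: trait_z ~ dosage + modifier + dosage x modifier + covariates
on the fully adjusted covariate set.  The reported interaction p-value is the
product-term coefficient's only.

Modifier coding: gender and site as indicators; "obesity" as the indicator
BMI >= 25 kg/m^2 (the Asian-Indian overweight cut-off; configurable); fat
intake z-standardized; physical activity ordinal 0-3.  No multiple-testing
correction is applied across the screen, mirroring the main analysis; the
screen reports how many tests it ran.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reference
from ._validation import ValidationError
from .association import MODEL2, ModelSpec, fit_additive_model, prepare_traits

__all__ = [
    "InteractionResult",
    "MODIFIERS",
    "stratified_association",
    "interaction_test",
    "interaction_screen",
    "DEFAULT_OBESITY_THRESHOLD",
]

#: BMI cut-off (kg/m^2) defining the "obesity" modifier.
DEFAULT_OBESITY_THRESHOLD = 25.0

#: Recognized modifier names for the screen.
MODIFIERS = ("gender", "site", "obesity", "fat_intake", "physical_activity")


@dataclass(frozen=True)
class InteractionResult:
    """Product-term estimate for one (variant, trait, modifier) triple."""

    rsid: str
    trait: str
    modifier: str
    beta: float
    se: float
    p: float
    n_used: int
    main_dosage_beta: float
    main_modifier_beta: float


def _drop(spec: ModelSpec, column: str) -> ModelSpec:
    return ModelSpec(spec.model_id, tuple(c for c in spec.covariates if c != column))


def stratified_association(
    G: pd.DataFrame,
    cohort: pd.DataFrame,
    trait_z,
    trait: str,
    stratum_var: str,
    spec: ModelSpec = MODEL2,
    min_n: int = 100,
):
    """Per-stratum additive fits with the stratifying covariate dropped.

    Returns ``{stratum_label: DataFrame}``; strata below ``min_n`` samples
    are skipped (reported as an empty frame with a ``skipped`` marker
    attribute left to the caller via absence).
    """
    if stratum_var not in ("gender", "site"):
        raise ValidationError("stratification supported for gender and site")
    sub_spec = _drop(spec, stratum_var)
    z = np.asarray(trait_z, dtype=float)
    out = {}
    for label in cohort[stratum_var].dropna().unique():
        mask = (cohort[stratum_var] == label).to_numpy()
        if mask.sum() < min_n:
            out[label] = None  # skipped: too few persons
            continue
        rows = []
        for rsid in G.columns:
            res = fit_additive_model(
                z[mask], G[rsid].to_numpy(dtype=float)[mask], cohort[mask], sub_spec,
                rsid=rsid, trait=trait,
            )
            rows.append(res.__dict__ | {"stratum": label})
        out[label] = pd.DataFrame(rows)
    return out


def _modifier_values(cohort: pd.DataFrame, modifier: str, obesity_threshold: float) -> np.ndarray:
    if modifier == "gender":
        return cohort["gender"].map({"male": 0.0, "female": 1.0}).to_numpy(dtype=float)
    if modifier == "site":
        return cohort["site"].map({"urban": 0.0, "rural": 1.0}).to_numpy(dtype=float)
    if modifier == "obesity":
        bmi = cohort["bmi"].to_numpy(dtype=float)
        return np.where(np.isnan(bmi), np.nan, (bmi >= obesity_threshold).astype(float))
    if modifier == "fat_intake":
        x = cohort["fat_intake"].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        return (x - obs.mean()) / obs.std(ddof=1)
    if modifier == "physical_activity":
        return cohort["physical_activity"].to_numpy(dtype=float)
    raise ValidationError(f"unknown modifier {modifier!r}")


def interaction_test(
    dosage,
    modifier: str,
    trait_z,
    cohort: pd.DataFrame,
    spec: ModelSpec = MODEL2,
    rsid: str = "x",
    trait: str = "trait",
    obesity_threshold: float = DEFAULT_OBESITY_THRESHOLD,
) -> InteractionResult:
    """Product-term test of effect modification on the adjusted model.

    The design holds dosage and modifier main effects, their product, and the
    covariate block (with the modifier's own covariate column removed to
    avoid duplicating it; BMI stays in the design when the modifier is the
    derived obesity indicator).
    """
    m = _modifier_values(cohort, modifier, obesity_threshold)
    m_obs = m[~np.isnan(m)]
    if np.unique(m_obs).size < 2:
        raise ValidationError(f"modifier {modifier!r} is constant")
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(trait_z, dtype=float)
    sub_spec = _drop(spec, modifier) if modifier in spec.covariates else spec

    from .association import build_design  # local import to keep surface tidy

    design = build_design(cohort, sub_spec.covariates)
    design = design.copy()
    design.insert(0, "_modifier", m)
    design.insert(0, "_product", d * m)
    frame = design.copy()
    frame.insert(0, "_dosage", d)
    frame.insert(0, "_y", y)
    frame = frame.dropna()
    if len(frame) <= frame.shape[1]:
        raise ValidationError("too few complete cases")
    import statsmodels.api as sm

    X = sm.add_constant(frame.drop(columns="_y"), has_constant="add")
    from .association import _check_rank

    _check_rank(X)
    fit = sm.OLS(frame["_y"].to_numpy(), X.to_numpy()).fit()
    names = list(X.columns)
    jp, jd, jm = names.index("_product"), names.index("_dosage"), names.index("_modifier")
    return InteractionResult(
        rsid,
        trait,
        modifier,
        float(fit.params[jp]),
        float(fit.bse[jp]),
        float(fit.pvalues[jp]),
        len(frame),
        float(fit.params[jd]),
        float(fit.params[jm]),
    )


def interaction_screen(
    G: pd.DataFrame,
    cohort: pd.DataFrame,
    panel: pd.DataFrame,
    traits=reference.TRAITS,
    modifiers=MODIFIERS,
    spec: ModelSpec = MODEL2,
    obesity_threshold: float = DEFAULT_OBESITY_THRESHOLD,
    skew_threshold: float = 1.0,
    forced_log=reference.LOG_TRAITS,
) -> pd.DataFrame:
    """All (variant, trait, modifier) product-term tests; annotates n_tests."""
    z, _ = prepare_traits(cohort, traits, skew_threshold, forced_log)
    rows = []
    rsids = [r for r in panel["rsid"] if r in G.columns]
    for rsid in rsids:
        d = G[rsid].to_numpy(dtype=float)
        for trait in traits:
            for modifier in modifiers:
                res = interaction_test(
                    d, modifier, z[trait], cohort, spec, rsid=rsid, trait=trait,
                    obesity_threshold=obesity_threshold,
                )
                rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    out["n_tests"] = len(out)
    return out
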