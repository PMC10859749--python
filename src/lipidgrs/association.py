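"""Per-variant additive-model association of standardized lipid traits.

Each variant is tested by ordinary least squares of the z-standardized
(log-transformed where skewed) trait on minor-allele dosage plus a covariate
block, on complete cases.  Two adjustment models mirror the study design:

* Model 1 — age, gender, site (urban/rural);
* Model 2 — Model 1 plus fat intake, physical activity, BMI, alcohol,
  smoking, hypertension and diabetes.

The dosage coefficient (per-allele effect in trait-SD units), its standard
error and a two-sided t-test p-value with residual degrees of freedom are
reported.  Categorical covariates are indicator-coded; physical activity is
ordinal 0-3 by default (indicator coding by option).  No correction for
multiple testing is applied across the panel: the variants are established
loci being validated individually at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import reference
from ._validation import CollinearityError, ValidationError
from .transforms import log_transform_if_skewed, z_standardize

__all__ = [
    "ModelSpec",
    "MODEL1",
    "MODEL2",
    "AssociationResult",
    "build_design",
    "fit_additive_model",
    "prepare_traits",
    "run_panel",
]


@dataclass(frozen=True)
class ModelSpec:
    """Adjustment model: an id and the covariate columns it includes."""

    model_id: int
    covariates: tuple

    def __post_init__(self):
        if len(set(self.covariates)) != len(self.covariates):
            raise ValidationError("duplicate covariates in model spec")


MODEL1 = ModelSpec(1, ("age", "gender", "site"))
MODEL2 = ModelSpec(
    2,
    (
        "age",
        "gender",
        "site",
        "fat_intake",
        "physical_activity",
        "bmi",
        "alcohol",
        "smoking",
        "hypertension",
        "diabetes",
    ),
)

MODELS = {1: MODEL1, 2: MODEL2}


@dataclass(frozen=True)
class AssociationResult:
    """One (variant, trait, model) regression summary.

    ``beta`` is the per-minor-allele effect in trait-SD units; ``p`` is the
    two-sided t-test p-value on residual degrees of freedom; ``n_used`` the
    complete-case count.  ``note`` is non-empty for skipped fits
    (e.g. "monomorphic").
    """

    rsid: str
    trait: str
    model: int
    beta: float
    se: float
    p: float
    n_used: int
    note: str = ""


_CATEGORY_CODES = {
    "gender": {"male": 0.0, "female": 1.0},
    "site": {"urban": 0.0, "rural": 1.0},
}


def build_design(cohort: pd.DataFrame, covariates, activity_coding: str = "ordinal") -> pd.DataFrame:
    """Numeric covariate design block (no intercept column).

    gender -> female indicator, site -> rural indicator, physical activity
    ordinal 0-3 (or three indicators with "inactive" as reference when
    ``activity_coding="indicator"``), binaries passed through as 0/1.
    """
    cols = {}
    for cov in covariates:
        if cov not in cohort.columns:
            raise ValidationError(f"covariate column {cov!r} missing from cohort table")
        col = cohort[cov]
        if cov in _CATEGORY_CODES:
            codes = _CATEGORY_CODES[cov]
            if col.dtype == object:
                unknown = set(col.dropna().unique()) - set(codes)
                if unknown:
                    raise ValidationError(f"unknown {cov} labels: {sorted(unknown)}")
                col = col.map(codes)
            label = {"gender": "gender_female", "site": "site_rural"}[cov]
            cols[label] = col.astype(float)
        elif cov == "physical_activity" and activity_coding == "indicator":
            pa = col.astype(float)
            for level in (1, 2, 3):
                cols[f"physical_activity_{level}"] = (pa == level).astype(float)
        else:
            cols[cov] = col.astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def _check_rank(X: pd.DataFrame):
    mat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) == mat.shape[1]:
        return
    # name the offenders: columns perfectly explained by the remaining ones
    offenders = []
    for j, name in enumerate(X.columns):
        others = np.delete(mat, j, axis=1)
        resid = mat[:, j] - others @ np.linalg.lstsq(others, mat[:, j], rcond=None)[0]
        denom = np.var(mat[:, j])
        if denom == 0 or np.var(resid) / denom < 1e-10:
            offenders.append(name)
    raise CollinearityError(offenders or list(X.columns))


def fit_additive_model(
    trait_z,
    dosage,
    cohort: pd.DataFrame | None,
    spec: ModelSpec | None,
    rsid: str = "x",
    trait: str = "trait",
    xname: str = "dosage",
    activity_coding: str = "ordinal",
) -> AssociationResult:
    """OLS of a standardized trait on one primary regressor plus covariates.

    Complete-case rows only.  A constant primary regressor (e.g. a
    monomorphic variant) is skipped with a flag rather than fitted.
    ``cohort``/``spec`` may be None for an unadjusted fit.
    """
    y = np.asarray(trait_z, dtype=float)
    x = np.asarray(dosage, dtype=float)
    if spec is not None and cohort is not None and spec.covariates:
        design = build_design(cohort, spec.covariates, activity_coding)
    else:
        design = pd.DataFrame(index=pd.RangeIndex(len(y)))
    model_id = spec.model_id if spec is not None else 0
    frame = design.copy()
    frame.insert(0, xname, x)
    frame.insert(0, "_y", y)
    frame = frame.dropna()
    n_used = len(frame)
    if n_used <= frame.shape[1]:  # parameters incl. intercept
        raise ValidationError("too few complete cases for the design")
    xs = frame[xname].to_numpy()
    if np.unique(xs).size < 2:
        return AssociationResult(rsid, trait, model_id, float("nan"), float("nan"), float("nan"), n_used, "monomorphic")
    X = sm.add_constant(frame.drop(columns="_y"), has_constant="add")
    _check_rank(X)
    fit = sm.OLS(frame["_y"].to_numpy(), X.to_numpy()).fit()
    j = list(X.columns).index(xname)
    return AssociationResult(
        rsid,
        trait,
        model_id,
        float(fit.params[j]),
        float(fit.bse[j]),
        float(fit.pvalues[j]),
        n_used,
    )


def prepare_traits(
    cohort: pd.DataFrame,
    traits=reference.TRAITS,
    skew_threshold: float = 1.0,
    forced_log=reference.LOG_TRAITS,
):
    """Standardize each trait, log-transforming per the skewness rule.

    ``forced_log`` pins traits to the log scale regardless of sample skew
    (the conventional choice for TG and VLDL-C); pass ``forced_log=None`` to
    let the skewness rule decide everywhere.  Returns
    ``(z_by_trait, transformed_flags)``.
    """
    z = {}
    flags = {}
    for trait in traits:
        if trait not in cohort.columns:
            raise ValidationError(f"trait column {trait!r} missing")
        force = (trait in forced_log) if forced_log is not None else None
        vals, transformed = log_transform_if_skewed(
            cohort[trait].to_numpy(dtype=float), skew_threshold, force=force
        )
        z[trait] = z_standardize(vals)
        flags[trait] = transformed
    return z, flags


def run_panel(
    G: pd.DataFrame,
    cohort: pd.DataFrame,
    panel: pd.DataFrame,
    traits=reference.TRAITS,
    models=(1, 2),
    skew_threshold: float = 1.0,
    forced_log=reference.LOG_TRAITS,
    activity_coding: str = "ordinal",
) -> pd.DataFrame:
    """Fit every (variant, trait, model) cell; deterministic row order.

    Variants are taken in panel order (only those present in ``G``), traits
    and models in the given order — 12 x 5 x 2 = 120 rows for the full
    design.
    """
    z, flags = prepare_traits(cohort, traits, skew_threshold, forced_log)
    rows = []
    rsids = [r for r in panel["rsid"] if r in G.columns]
    for rsid in rsids:
        dosage = G[rsid].to_numpy(dtype=float)
        for trait in traits:
            for model_id in models:
                res = fit_additive_model(
                    z[trait], dosage, cohort, MODELS[model_id], rsid=rsid, trait=trait,
                    activity_coding=activity_coding,
                )
                rows.append(res.__dict__ | {"log_transformed": flags[trait]})
    return pd.DataFrame(rows)
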