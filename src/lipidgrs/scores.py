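"""Unweighted and weighted allelic risk scores for lipid traits.

A variant enters a trait's score only when it is significant in *both*
adjustment models for that trait (dual-significance selection).  Each selected
variant is oriented to its risk allele — the allele whose per-allele effect
moves the trait in the adverse direction (up for TC/TG/LDL/VLDL, down for
HDL); that allele may be the major one.  The unweighted score (uGRS) is the
sum of risk-allele dosages; the weighted score (wGRS) is

    wGRS = w_1 a_1 + ... + w_i a_i

with w_i = |beta_i| from the configured source model (fully adjusted by
default) and a_i the risk-allele count.  Orienting to the adverse direction
makes every weight positive and gives the HDL score its expected *negative*
association with HDL-C.  Missing genotypes are imputed at the expected
oriented dosage (2 x risk-allele frequency) by default, standard scoring
practice that preserves sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from ._validation import OrientationError, ValidationError
from .association import MODEL1, AssociationResult, ModelSpec, fit_additive_model

__all__ = [
    "ADVERSE_DIRECTION",
    "ScoreDefinition",
    "select_validated_variants",
    "orient_risk_alleles",
    "build_score_definition",
    "oriented_dosages",
    "compute_ugrs",
    "compute_wgrs",
    "grs_association",
]

#: Sign of the adverse change per trait: higher is worse except HDL-C.
ADVERSE_DIRECTION = {"TC": 1.0, "TG": 1.0, "LDL": 1.0, "VLDL": 1.0, "HDL": -1.0}


@dataclass(frozen=True)
class ScoreDefinition:
    """Oriented, weighted variant set realizing a trait's risk score.

    ``counted_is_minor[i]`` says whether the counted (risk) allele of
    ``rsids[i]`` is the minor allele; when False the oriented dosage is
    ``2 - minor_dosage``.  ``rescale="count_normalized"`` multiplies the
    weighted sum by i / sum(w), putting the wGRS back on the allele-count
    scale.
    """

    trait: str
    rsids: tuple
    counted_is_minor: tuple
    weights: tuple
    weighting: str = "weighted"  # "unweighted" | "weighted"
    rescale: str = "none"  # "none" | "count_normalized"
    source_model: int = 2
    alpha: float = 0.05

    def __post_init__(self):
        if not self.rsids:
            raise ValidationError("score definition needs at least one variant")
        if len(self.rsids) != len(self.counted_is_minor) or len(self.rsids) != len(self.weights):
            raise ValidationError("rsids, orientation flags and weights must align")
        if self.weighting == "weighted" and any(w <= 0 for w in self.weights):
            raise ValidationError("weights must be strictly positive in weighted mode")


def select_validated_variants(results: pd.DataFrame, trait: str, alpha: float = 0.05, panel_order=None):
    """Variants with p < alpha in both models for ``trait``, in panel order."""
    sub = results[results["trait"] == trait]
    models = set(sub["model"].unique())
    if not {1, 2} <= models:
        raise ValidationError(f"results must contain both models for {trait} (have {sorted(models)})")
    by_model = {m: sub[sub["model"] == m].set_index("rsid")["p"] for m in (1, 2)}
    order = list(panel_order) if panel_order is not None else list(dict.fromkeys(sub["rsid"]))
    return [
        rsid
        for rsid in order
        if rsid in by_model[1].index
        and rsid in by_model[2].index
        and by_model[1][rsid] < alpha
        and by_model[2][rsid] < alpha
    ]


def orient_risk_alleles(results: pd.DataFrame, trait: str, rsids, weight_model: int = 2) -> pd.DataFrame:
    """Risk-allele orientation and positive weights for the given variants.

    Uses the sign of the ``weight_model`` estimate relative to the trait's
    adverse direction.  The ``coded_allele`` column of ``results`` (default
    "minor") states which allele each beta counts; the counted risk allele is
    the coded allele when the effect is adverse, the opposite otherwise.
    """
    if trait not in ADVERSE_DIRECTION:
        raise ValidationError(f"unknown trait {trait!r}")
    direction = ADVERSE_DIRECTION[trait]
    sub = results[(results["trait"] == trait) & (results["model"] == weight_model)].set_index("rsid")
    rows = []
    for rsid in rsids:
        if rsid not in sub.index:
            raise ValidationError(f"no model-{weight_model} estimate for {rsid} / {trait}")
        row = sub.loc[rsid]
        beta = float(row["beta"])
        if beta == 0.0:
            raise OrientationError(f"zero estimated effect for {rsid} / {trait}: orientation undefined")
        coded = row.get("coded_allele", "minor") if hasattr(row, "get") else "minor"
        if pd.isna(coded):
            coded = "minor"
        adverse_is_coded = beta * direction > 0
        counted = coded if adverse_is_coded else ("major" if coded == "minor" else "minor")
        rows.append({"rsid": rsid, "counted_allele": counted, "weight": abs(beta)})
    return pd.DataFrame(rows)


def build_score_definition(
    results: pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
    weight_model: int = 2,
    weighting: str = "weighted",
    rescale: str = "none",
    panel_order=None,
) -> ScoreDefinition:
    """Dual-significance selection + orientation in one step."""
    selected = select_validated_variants(results, trait, alpha, panel_order)
    if not selected:
        raise ValidationError(f"no variant passes dual-model significance for {trait} at alpha={alpha}")
    oriented = orient_risk_alleles(results, trait, selected, weight_model)
    return ScoreDefinition(
        trait,
        tuple(oriented["rsid"]),
        tuple(oriented["counted_allele"] == "minor"),
        tuple(oriented["weight"]),
        weighting=weighting,
        rescale=rescale,
        source_model=weight_model,
        alpha=alpha,
    )


def oriented_dosages(G: pd.DataFrame, definition: ScoreDefinition, impute_missing: bool = True) -> pd.DataFrame:
    """Risk-allele dosages for the definition's variants.

    Missing genotypes are imputed at twice the observed risk-allele frequency
    when ``impute_missing`` (default); otherwise they stay NaN and the
    resulting scores are NaN for incomplete persons (complete-case mode).
    """
    cols = {}
    for rsid, is_minor in zip(definition.rsids, definition.counted_is_minor):
        if rsid not in G.columns:
            raise ValidationError(f"genotypes missing score variant {rsid}")
        d = G[rsid].to_numpy(dtype=float)
        a = d if is_minor else 2.0 - d
        if impute_missing and np.isnan(a).any():
            obs = a[~np.isnan(a)]
            if obs.size == 0:
                raise ValidationError(f"{rsid}: no observed genotypes to impute from")
            a = np.where(np.isnan(a), obs.mean(), a)
        cols[rsid] = a
    return pd.DataFrame(cols, index=G.index)


def _score(G, definition, impute_missing, weights) -> pd.Series:
    A = oriented_dosages(G, definition, impute_missing)
    score = A.to_numpy() @ weights
    # a person with no observed genotype at all has no defined score even
    # under imputation
    all_missing = G[list(definition.rsids)].isna().all(axis=1).to_numpy()
    return pd.Series(np.where(all_missing, np.nan, score), index=G.index, name="score")


def compute_ugrs(G: pd.DataFrame, definition: ScoreDefinition, impute_missing: bool = True) -> pd.Series:
    """Unweighted score: sum of risk-allele dosages, in [0, 2i]."""
    return _score(G, definition, impute_missing, np.ones(len(definition.rsids)))


def compute_wgrs(G: pd.DataFrame, definition: ScoreDefinition, impute_missing: bool = True) -> pd.Series:
    """Weighted score sum_i w_i a_i (optionally count-normalized)."""
    w = np.asarray(definition.weights, dtype=float)
    if definition.rescale == "count_normalized":
        w = w * len(w) / w.sum()
    elif definition.rescale != "none":
        raise ValidationError(f"unknown rescale mode {definition.rescale!r}")
    return _score(G, definition, impute_missing, w)


def grs_association(
    score: pd.Series,
    cohort: pd.DataFrame,
    trait_z,
    trait: str,
    spec: ModelSpec = MODEL1,
    standardize_score: bool = False,
    min_n: int = 30,
) -> AssociationResult:
    """OLS of the standardized trait on the (raw) score + Model 1 covariates."""
    s = np.asarray(score, dtype=float)
    if np.sum(~np.isnan(s)) < min_n:
        raise ValidationError("score defined for too few persons")
    if standardize_score:
        obs = s[~np.isnan(s)]
        s = (s - obs.mean()) / obs.std(ddof=1)
    return fit_additive_model(
        trait_z, s, cohort, spec, rsid="score", trait=trait, xname="score"
    )
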