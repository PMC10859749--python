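"""Lipid trait derivation, transformation and unit conversion.

Lipid panels in epidemiological cohorts are reported in mg/dL.  Total
cholesterol (TC), HDL-C and LDL-C are usually close to normal, while
triglycerides (TG) and VLDL-C are right-skewed and analysed on the natural-log
scale.  Association models are fitted on z-standardized (possibly
log-transformed) traits, so effect sizes come out in trait-SD units; this
module converts them back to interpretable quantities — mg/dL differences for
normal traits, multiplicative fold-changes for log traits.

Conventions: natural logarithms throughout; sample SD uses the n-1
denominator; the geometric SD (GSD) of a log-normal trait is
``exp(sd(log x))`` and is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._validation import ValidationError

__all__ = [
    "TraitSummary",
    "friedewald_ldl",
    "vldl_from_tg",
    "log_transform_if_skewed",
    "z_standardize",
    "effect_in_original_units",
]

#: Triglyceride ceiling (mg/dL) above which the Friedewald approximation
#: VLDL-C = TG/5 breaks down and LDL-C is not reported.
FRIEDEWALD_TG_CEILING = 400.0


@dataclass(frozen=True)
class TraitSummary:
    """Location/scale summary of one lipid trait.

    For ``scale == "normal"``, ``mean``/``sd`` are the arithmetic mean and SD
    in mg/dL.  For ``scale == "log"``, ``mean`` is the geometric mean (mg/dL)
    and ``sd`` the geometric SD (dimensionless, > 1 for non-degenerate data).
    """

    trait: str
    scale: str  # "normal" | "log"
    mean: float
    sd: float

    def __post_init__(self):
        if self.scale not in ("normal", "log"):
            raise ValidationError(f"unknown trait scale {self.scale!r}")
        if not self.sd > 0:
            raise ValidationError("trait SD must be positive")
        if self.scale == "log" and self.sd <= 1:
            raise ValidationError("geometric SD must exceed 1")

    @classmethod
    def from_sample(cls, trait: str, values, scale: str) -> "TraitSummary":
        x = np.asarray(values, dtype=float)
        x = x[~np.isnan(x)]
        if x.size < 2:
            raise ValidationError("need at least two observations")
        if scale == "log":
            if np.any(x <= 0):
                raise ValidationError("log-scale trait requires positive values")
            lx = np.log(x)
            return cls(trait, "log", float(np.exp(lx.mean())), float(np.exp(lx.std(ddof=1))))
        return cls(trait, "normal", float(x.mean()), float(x.std(ddof=1)))


def friedewald_ldl(tc, hdl, tg, tg_ceiling: float = FRIEDEWALD_TG_CEILING):
    """LDL-C = TC - HDL-C - TG/5 (mg/dL).

    Entries with TG at or above ``tg_ceiling`` (default 400 mg/dL) are outside
    the equation's validity range and come back as NaN, as do non-positive
    derived values; callers treat NaN as the flagged-invalid marker.
    Scalar inputs return a scalar.
    """
    tc_a, hdl_a, tg_a = np.broadcast_arrays(
        np.asarray(tc, dtype=float), np.asarray(hdl, dtype=float), np.asarray(tg, dtype=float)
    )
    if np.any(tc_a[~np.isnan(tc_a)] <= 0) or np.any(hdl_a[~np.isnan(hdl_a)] <= 0) or np.any(
        tg_a[~np.isnan(tg_a)] <= 0
    ):
        raise ValidationError("lipid inputs must be positive")
    ldl = tc_a - hdl_a - tg_a / 5.0
    invalid = (tg_a >= tg_ceiling) | (ldl <= 0)
    ldl = np.where(invalid, np.nan, ldl)
    if np.ndim(tc) == 0 and np.ndim(hdl) == 0 and np.ndim(tg) == 0:
        return float(ldl)
    return ldl


def vldl_from_tg(tg):
    """VLDL-C = TG/5 (mg/dL), the Friedewald convention."""
    tg_a = np.asarray(tg, dtype=float)
    if np.any(tg_a[~np.isnan(tg_a)] <= 0):
        raise ValidationError("triglycerides must be positive")
    out = tg_a / 5.0
    return float(out) if np.ndim(tg) == 0 else out


def log_transform_if_skewed(x, skew_threshold: float = 1.0, force: bool | None = None):
    """Natural-log transform a trait when its sample skewness exceeds a cutoff.

    Returns ``(values, transformed)``.  ``force=True``/``False`` overrides the
    skewness rule (used to pin the conventional per-trait choices, e.g. TG and
    VLDL-C on the log scale regardless of the realized sample skew).
    """
    arr = np.asarray(x, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size < 3:
        raise ValidationError("need at least three observations to assess skewness")
    if force is None:
        transformed = bool(stats.skew(obs, bias=False) > skew_threshold)
    else:
        transformed = bool(force)
    if transformed:
        if np.any(obs <= 0):
            raise ValidationError("cannot log-transform non-positive values")
        return np.log(arr), True
    return arr.copy(), False


def z_standardize(x):
    """Center and scale to sample mean 0, SD 1 (n-1 denominator).

    NaNs are ignored in the moments and propagated through.
    """
    arr = np.asarray(x, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size < 2:
        raise ValidationError("need at least two observations")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot standardize a constant vector")
    return (arr - obs.mean()) / sd


def effect_in_original_units(beta_std: float, summary: TraitSummary) -> float:
    """Convert a per-unit effect on the z-scale back to interpretable units.

    Normal traits: ``beta_std * SD`` mg/dL per unit of the regressor.
    Log traits: the multiplicative fold-change ``GSD ** beta_std``
    (= exp(beta_std * ln GSD)); e.g. beta 0.21 with GSD 1.60 is a 1.10-fold
    (+10.4%) change per allele.  Fold-changes, not mg/dL, are the honest unit
    for a log-scale fit.
    """
    if summary.scale == "normal":
        return float(beta_std * summary.sd)
    return float(summary.sd**beta_std)
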