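"""Analytic power for additive quantitative-trait association.

Score-test framework: for a variant explaining a fraction r^2 of the variance
of a unit-variance trait, the association chi-square (1 df) has noncentrality
lambda = n * r^2 / (1 - r^2), and power at two-sided level alpha is

    power = P( chi2_1(lambda) > chi2_{1, 1-alpha} ).

Given a per-allele effect beta (trait-SD units) at minor-allele frequency p
under HWE, r^2 = beta^2 * 2 p (1 - p).  The inverse problem — the minimum
detectable r^2 at a target power — is solved by root finding on the same
formula.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import optimize, stats

from ._validation import ValidationError

__all__ = ["PowerSpec", "r2_from_beta_maf", "power_additive", "min_detectable_r2"]


@dataclass(frozen=True)
class PowerSpec:
    """Power-calculation inputs: give ``r2`` or (``beta``, ``maf``)."""

    n: int
    alpha: float = 0.05
    r2: float | None = None
    beta: float | None = None
    maf: float | None = None

    def resolved_r2(self) -> float:
        if self.r2 is not None:
            return self.r2
        if self.beta is None or self.maf is None:
            raise ValidationError("specify r2 or both beta and maf")
        return r2_from_beta_maf(self.beta, self.maf)


def r2_from_beta_maf(beta: float, maf: float) -> float:
    """Variance fraction beta^2 * 2p(1-p) for a unit-variance trait."""
    if not 0.0 < maf <= 0.5:
        raise ValidationError("MAF must be in (0, 0.5]")
    return beta * beta * 2.0 * maf * (1.0 - maf)


def power_additive(
    n: int | None = None,
    *,
    r2: float | None = None,
    beta: float | None = None,
    maf: float | None = None,
    alpha: float = 0.05,
    spec: PowerSpec | None = None,
) -> float:
    """Two-sided power of the 1-df additive association test."""
    if spec is None:
        if n is None:
            raise ValidationError("sample size required")
        spec = PowerSpec(n=n, alpha=alpha, r2=r2, beta=beta, maf=maf)
    if spec.n <= 2:
        raise ValidationError("n must exceed 2")
    if not 0.0 < spec.alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    r2v = spec.resolved_r2()
    if r2v < 0:
        raise ValidationError("r2 cannot be negative")
    if r2v == 0.0:
        return spec.alpha  # null case: rejection at the nominal level
    if r2v >= 1.0:
        raise ValidationError("r2 must be below 1")
    lam = spec.n * r2v / (1.0 - r2v)
    crit = stats.chi2.ppf(1.0 - spec.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=lam))


def min_detectable_r2(n: int, alpha: float = 0.05, target_power: float = 0.80) -> float:
    """Smallest variance fraction reaching ``target_power`` at level alpha.

    Root-found to |power - target| < 1e-6; round-trips through
    :func:`power_additive`.  A target at or below alpha is reached in the
    r2 -> 0 limit and returns 0.
    """
    if not 0.0 < target_power < 1.0:
        raise ValidationError("target power must be in (0, 1)")
    if target_power <= alpha:
        return 0.0
    lo, hi = 1e-12, 1.0 - 1e-9
    if power_additive(n, r2=hi, alpha=alpha) < target_power:
        raise ValidationError(f"target power {target_power} unattainable at n={n}")
    r2 = optimize.brentq(
        lambda r: power_additive(n, r2=r, alpha=alpha) - target_power, lo, hi, xtol=1e-14
    )
    return float(r2)
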