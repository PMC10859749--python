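"""Variant-level quality control.

Call-rate filtering, minor-allele-frequency estimation, Hardy-Weinberg
equilibrium (HWE) testing — per site stratum (rural, urban) and combined —
with a Sidak-corrected significance threshold.

Two HWE tests are provided: the 1-df Pearson chi-square against the genotype
counts expected from the estimated allele frequency, and the exact test that
conditions on the observed allele counts and enumerates the heterozygote-count
distribution (standard or mid-p).  The default ``"auto"`` method uses the
exact test whenever the expected minor-homozygote count falls below 5,
the usual small-count practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from ._validation import ValidationError

__all__ = [
    "GenotypeCounts",
    "HWEResult",
    "call_rate",
    "estimate_maf",
    "hwe_test",
    "sidak_threshold",
    "qc_filter",
    "STUDY_HWE_THRESHOLD",
]

#: The study's printed Sidak-corrected HWE significance threshold.  It is not
#: the m=12, alpha=0.05 value (0.00427); the number of tests behind it is
#: unstated, so the literal is exposed as the default filter cutoff.
STUDY_HWE_THRESHOLD = 0.0018


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts at one biallelic site (minor-allele coded)."""

    n_major_hom: int
    n_het: int
    n_minor_hom: int
    n_missing: int = 0

    def __post_init__(self):
        if min(self.n_major_hom, self.n_het, self.n_minor_hom, self.n_missing) < 0:
            raise ValidationError("genotype counts must be nonnegative")

    @property
    def n_observed(self) -> int:
        return self.n_major_hom + self.n_het + self.n_minor_hom

    @classmethod
    def from_dosages(cls, dosages) -> "GenotypeCounts":
        d = np.asarray(dosages, dtype=float)
        missing = int(np.isnan(d).sum())
        d = d[~np.isnan(d)]
        if not np.isin(d, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be 0, 1, 2 or missing")
        return cls(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()), missing)


@dataclass(frozen=True)
class HWEResult:
    statistic: float  # chi-square statistic; NaN for the exact test
    p: float
    method: str
    warning: str = ""


def call_rate(G: pd.DataFrame) -> pd.Series:
    """Per-variant fraction of non-missing genotypes."""
    if len(G) == 0:
        raise ValidationError("genotype matrix has no samples")
    return G.notna().mean(axis=0).rename("call_rate")


def estimate_maf(counts: GenotypeCounts):
    """Allele frequency of the coded allele, reflected into [0, 0.5].

    Returns ``(maf, coded_is_minor)``: when the coded allele turns out to be
    the commoner one its frequency is reflected and ``coded_is_minor`` is
    False.
    """
    n = counts.n_observed
    if n < 1:
        raise ValidationError("MAF undefined: no observed genotypes")
    freq = (2 * counts.n_minor_hom + counts.n_het) / (2 * n)
    if freq > 0.5:
        return 1.0 - freq, False
    return freq, True


def _hwe_chisq(counts: GenotypeCounts) -> HWEResult:
    n = counts.n_observed
    q, _ = estimate_maf(counts)
    p = 1.0 - q
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([counts.n_major_hom, counts.n_het, counts.n_minor_hom], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = float(np.nansum(np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)))
    return HWEResult(stat, float(stats.chi2.sf(stat, df=1)), "chisq")


def _exact_het_distribution(n: int, n_minor_alleles: int):
    """Exact distribution of the heterozygote count given allele counts.

    P(h | n, r) = [n! / (n_rr! h! n_cc!)] 2^h r! (2n-r)! / (2n)!, over h with
    the parity of r and 0 <= h <= min(r, 2n - r).
    """
    r = n_minor_alleles
    h = np.arange(r % 2, min(r, 2 * n - r) + 1, 2)
    n_rr = (r - h) // 2
    n_cc = n - h - n_rr
    logp = (
        special.gammaln(n + 1)
        - special.gammaln(h + 1)
        - special.gammaln(n_rr + 1)
        - special.gammaln(n_cc + 1)
        + h * np.log(2.0)
        + special.gammaln(r + 1)
        + special.gammaln(2 * n - r + 1)
        - special.gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    return h, probs / probs.sum()


def _hwe_exact(counts: GenotypeCounts, midp: bool = False) -> HWEResult:
    n = counts.n_observed
    r = 2 * counts.n_minor_hom + counts.n_het
    if min(r, 2 * n - r) == 0:
        return HWEResult(float("nan"), 1.0, "exact", warning="monomorphic")
    h, probs = _exact_het_distribution(n, min(r, 2 * n - r))
    p_obs = probs[h == counts.n_het][0]
    tol = 1e-12
    if midp:
        p = float(probs[probs < p_obs - tol].sum() + 0.5 * probs[np.abs(probs - p_obs) <= tol].sum())
    else:
        p = float(probs[probs <= p_obs + tol].sum())
    return HWEResult(float("nan"), min(p, 1.0), "exact-midp" if midp else "exact")


def hwe_test(counts: GenotypeCounts, method: str = "auto", midp: bool = False) -> HWEResult:
    """Test genotype counts against Hardy-Weinberg proportions.

    ``method``: ``"chisq"``, ``"exact"``, or ``"auto"`` (exact when the
    HWE-expected minor-homozygote count is below 5).  Monomorphic variants
    return p = 1 with a warning flag — no test is possible.
    """
    if counts.n_observed < 1:
        raise ValidationError("HWE test needs at least one observed genotype")
    q, _ = estimate_maf(counts)
    if q == 0.0:
        return HWEResult(0.0, 1.0, method, warning="monomorphic")
    if method == "auto":
        method = "exact" if counts.n_observed * q * q < 5 else "chisq"
    if method == "chisq":
        return _hwe_chisq(counts)
    if method == "exact":
        return _hwe_exact(counts, midp=midp)
    raise ValidationError(f"unknown HWE method {method!r}")


def sidak_threshold(alpha: float, m: int) -> float:
    """Sidak-corrected per-test threshold 1 - (1 - alpha)^(1/m)."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def qc_filter(
    G: pd.DataFrame,
    sites,
    min_call_rate: float = 0.95,
    hwe_threshold: float = STUDY_HWE_THRESHOLD,
    method: str = "auto",
):
    """Apply the variant QC rules; returns ``(retained_rsids, report)``.

    A variant is retained iff its call rate is >= ``min_call_rate`` and its
    HWE p-value is >= ``hwe_threshold`` in every stratum (rural, urban and
    combined — HWE must hold separately in each recruitment site and
    overall).
    """
    if not 0.0 < min_call_rate <= 1.0 or not 0.0 < hwe_threshold <= 1.0:
        raise ValidationError("thresholds must lie in (0, 1]")
    sites = np.asarray(sites)
    cr = call_rate(G)
    strata = {"combined": np.ones(len(G), dtype=bool)}
    for site in ("rural", "urban"):
        mask = sites == site
        if mask.any():
            strata[site] = mask
    rows = []
    for rsid in G.columns:
        d = G[rsid].to_numpy(dtype=float)
        counts = GenotypeCounts.from_dosages(d)
        maf, _ = estimate_maf(counts) if counts.n_observed else (float("nan"), True)
        row = {"rsid": rsid, "call_rate": float(cr[rsid]), "maf": maf}
        hwe_ok = True
        for name, mask in strata.items():
            res = hwe_test(GenotypeCounts.from_dosages(d[mask]), method=method)
            row[f"hwe_p_{name}"] = res.p
            hwe_ok &= res.p >= hwe_threshold
        row["pass_call_rate"] = row["call_rate"] >= min_call_rate
        row["pass_hwe"] = hwe_ok
        row["retained"] = row["pass_call_rate"] and hwe_ok
        rows.append(row)
    report = pd.DataFrame(rows)
    retained = report.loc[report["retained"], "rsid"].tolist()
    return retained, report
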