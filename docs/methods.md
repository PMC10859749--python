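# Methods

## The problem and the model

Small panels of established GWAS variants are routinely re-tested ("validated")
in new populations before being combined into genetic risk scores. This
package implements that workflow for five lipid traits (TC, TG, HDL-C, LDL-C,
VLDL-C) in a two-site (rural/urban) adult cohort design of n = 2,117 with a
12-variant panel.

Association is the additive model: for person *j* with minor-allele dosage
d<sub>j</sub> ∈ {0,1,2},

  z<sub>j</sub> = β d<sub>j</sub> + γ′c<sub>j</sub> + ε<sub>j</sub>,

fitted by OLS on the z-standardized trait (natural-log first where skewed),
complete cases only, with p-values from the t reference on residual degrees
of freedom (at n ≈ 2,100 the t/normal distinction is immaterial; t is the
OLS-exact choice). Model 1 adjusts for age, gender and site; Model 2 adds
fat intake, physical activity (ordinal 0–3; indicator coding available),
BMI, alcohol, smoking, hypertension and diabetes. No multiple-testing
correction is applied across the panel — the variants are individually
pre-established loci — so α = 0.05 throughout.

### Risk scores

A variant enters a trait's score only if p < 0.05 under **both** models
(dual-significance selection). Each selected variant is oriented to its
**risk allele**: the allele whose per-allele effect moves the trait in the
adverse direction (up for TC/TG/LDL/VLDL, down for HDL); this can be the
major allele, in which case the counted dosage is 2 − minor dosage. The
unweighted score sums risk-allele dosages (range [0, 2i]); the weighted score
is the raw sum Σ wᵢaᵢ with wᵢ = |β̂ᵢ| taken from the fully adjusted model
(configurable to Model 1; the orientation makes all weights positive). This
orientation rule is what produces the expected *negative* coefficient when an
HDL score built from HDL-lowering alleles is regressed on HDL-C — a
signed-weight scheme cannot. An optional count-normalized rescaling
(× i / Σw) is provided but off by default; the displayed raw-sum equation is
the reference behavior. Scores are regressed on the standardized trait with
Model 1 adjustment, raw (unstandardized) by default. Missing genotypes are
imputed at the expected oriented dosage (2 × risk-allele frequency), the
standard scoring practice that preserves n; complete-case mode is available.
A person with no observed genotype at any score variant gets an undefined
(NaN) score.

### Units

Fits are on the z-scale, so β is in trait-SD units. Back-conversion:
normal traits, β × SD in mg/dL; log traits, the geometric fold-change
GSD^β (= exp(β·ln GSD)). Reporting log-trait effects as fold-changes rather
than mg/dL is deliberate: an additive mg/dL reading of a log-scale β is not
well defined, and the fold-change reproduces the per-allele magnitudes the
trait summaries imply.

### Hardy–Weinberg QC

Genotype counts are tested against HWE proportions per recruitment site and
combined; a variant must pass everywhere and have call rate ≥ 0.95. Two
tests: the 1-df Pearson chi-square on expected counts from the estimated
allele frequency, and the exact test conditioning on observed allele counts,
P(h | n, r) ∝ 2^h n! / (n_rr! h! n_cc!), with the standard two-sided rule
(sum of outcome probabilities ≤ the observed one; mid-p variant available).
"auto" uses the exact test when the expected minor-homozygote count is
below 5. The default filter cutoff is 0.0018 — the study's printed
Sidak-corrected value. It does not equal 1 − 0.95^(1/12) = 0.00427, and the
number of tests behind it is unstated, so the literal is exposed as a named
default (`STUDY_HWE_THRESHOLD`) next to the generic `sidak_threshold(alpha, m)`
rather than silently re-derived.

### Interactions

Effect modification is screened with product terms on the fully adjusted
covariate set: trait ~ dosage + modifier + dosage×modifier + covariates,
reporting the product coefficient only. Binary modifiers are indicators
(gender, site, obesity); "obesity" is BMI ≥ 25 kg/m², the Asian-Indian
overweight cut-off, configurable, since no definition is given in the source
tables; fat intake enters standardized; physical activity ordinal. With a
binary modifier and a design saturated in the modifier, the product
coefficient equals the difference of stratum-specific slopes (asserted
against a brute-force OLS oracle in the tests). Stratified fits drop the
stratifying covariate and require a minimum stratum size (default 100). As
in the main analysis, the screen is uncorrected; the output annotates how
many tests were run.

### Power

Score-test framework: a variant explaining variance fraction r² of a
unit-variance trait yields a 1-df chi-square with noncentrality
λ = n r²/(1−r²); power = P(χ²₁(λ) > χ²₁,1−α). Two-sided α is assumed.
Given (β, MAF), r² = β²·2p(1−p). The minimum detectable r² inverts the
formula by root finding (|power − target| < 1e-6, round-trips through the
forward formula). At n = 2,117 and α = 0.05 this gives ≈ 99.6% power at
r² = 1% and a minimum detectable r² of ≈ 0.37% at 80% power; the analytic
value is cross-checked against the empirical rejection rate of the
generator + regression stack in the tests.

## The synthetic-cohort generator

The generator's defaults are the study conditions, embedded in
`reference.py`:

- **Genotypes**: dosage ~ Binomial(2, MAF) with the site-specific MAFs of the
  12-variant panel; HWE holds by construction. No linkage disequilibrium is
  simulated — the panel spans 9 chromosomes and the analysis treats variants
  independently (a correlation hook would slot into `simulate_genotypes`).
- **Covariates**: gender × site from the published cross-tab (42.37% rural,
  45.25% male); age (47.07 ± 12.99 y), BMI (24.91 ± 5.25 kg/m²), fat intake
  (31.09 ± 5.05 g/day) as truncated normals whose location is re-centered by
  root finding so the *truncated* mean equals the stated marginal (the
  truncation bounds are plausibility guards: age 18–95, BMI 12–55, fat
  5–70); physical activity (11.5/52.7/25.3/10.5%) and binary risk factors
  from their prevalences. Covariates are otherwise mutually independent:
  only marginals are published, and this is a stated fidelity limit (real
  BMI–site or fat–gender correlations are absent, so covariate adjustment
  in simulations is nearly orthogonal to dosage).
- **Phenotypes**: standardized latent trait per lipid,
  z = Σ β<sub>j</sub>(d<sub>j</sub> − d̄<sub>j</sub>) + Σ γ<sub>k</sub>c̃<sub>k</sub> + ε,
  residual SD defaulting to √(1 − explained variance) so Var(z) = 1. Normal
  traits are affinely rescaled to (mean, SD); log traits are
  exp(ln GM + ln GSD · z) with TG at GM 125.96 mg/dL, GSD 1.60 (the "(1.60)"
  in the trait table is a geometric SD per its geometric-mean footnote;
  natural logs throughout). The default per-allele effects are the published
  fully adjusted estimates for TC, HDL and log-TG (sign-flipped onto
  minor-allele coding for the three variants whose published estimates are
  major-allele coded); covariate effects default to zero because none are
  published. VLDL-C is TG/5 exactly; LDL-C is derived per person by
  Friedewald and set invalid (NaN) when TG ≥ 400 mg/dL or the derived value
  is non-positive (≈1% of persons at these TG parameters). LDL is therefore
  *not* an independently calibrated trait: its simulated mean and SD are
  whatever TC − HDL − TG/5 implies.
- **Missingness**: i.i.d. per call at 1 − call_rate. The pipeline default
  simulates at call rate 0.98: simulating exactly at the 0.95 filter
  threshold puts every variant on the boundary, where ~half fail by chance,
  which does not represent a panel that passed QC.

What passing tests on this generator do and do not show: they verify the
estimators, their calibration (type-I error, SE magnitudes, power) and all
score/selection logic under the published marginal structure; they cannot
validate behavior under population stratification, covariate–genotype
confounding, LD, or differential (non-random) missingness, none of which are
simulated.

## Numerical and design choices

- Sample SDs use n − 1; z-standardization ignores NaN and propagates it.
- Skewness rule: log-transform when bias-corrected sample skewness > 1.0
  (log-normal with GSD 1.60 has skewness ≈ 1.55); the pipeline pins TG and
  VLDL to the log scale by default (`forced_log`), matching the conventional
  per-trait choice and making the TG/VLDL analysis identity exact:
  z(log VLDL) = z(log TG − log 5) = z(log TG), so every TG association cell
  equals its VLDL cell on any dataset with VLDL = TG/5.
- Monomorphic variants are skipped with a flag, never fitted; rank-deficient
  designs raise a collinearity error naming the dependent columns.
- Determinism: one integer seed drives `numpy.random.default_rng`; identical
  seeds reproduce every table byte-for-byte.
- Report writers offer 2-dp "report" precision (the presentation convention
  of the published tables, whose rounding is why some printed conversions are
  only reproducible to ~rounding accuracy) and full-precision "machine" mode.
- Score-level mg/dL conversions printed in the source (36.31/40.62/33.97/
  10.64) are reproducible only approximately from the rounded published β and
  SD — exactly for none, within ~1% for TC — because they were evidently
  computed from unrounded internals; the package asserts rounding-limited
  agreement and does not tune toward the printed values.
- Problem sizes in the test suite and acceptance script (e.g. 200 replicate
  cohorts for SE recovery, 500–2,000 replicates for calibration checks,
  100k draws for closed-form frequency checks) were chosen so Monte Carlo
  error is comfortably below each assertion's tolerance while the whole
  suite stays desk-scale.

## Known limitations

- No population structure, relatedness, imputation or haplotypes; no
  sample-level QC (sex checks, heterozygosity, duplicates).
- Covariate joint structure beyond gender × site is not emulated.
- VCF support is read-only for analysis (plus a minimal writer used in
  round-trip tests); genotype CSV is the canonical interchange.
- Binary-trait and gene–environment power modes are out of scope.
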