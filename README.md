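# lipidgrs

Candidate-variant validation and allelic risk scores for blood-lipid traits,
built around the design of a rural–urban North Indian cohort study: 2,117
adults genotyped at 12 established lipid-associated GWAS variants and
phenotyped for total cholesterol (TC), triglycerides (TG), HDL-C, LDL-C and
VLDL-C.

The package is for statistical geneticists and genetic epidemiologists who
want a tested, reusable implementation of the whole small-panel validation
workflow:

- **Variant QC** — call rate, minor-allele frequency, Hardy–Weinberg
  equilibrium (1-df chi-square and heterozygote-conditional exact tests,
  tested per recruitment site and combined) with Sidak-corrected thresholds.
- **Trait preparation** — Friedewald LDL-C (`TC − HDL − TG/5`, invalid above
  TG 400 mg/dL), VLDL-C = TG/5, skewness-triggered log transformation, and
  z-standardization, so effects come out in trait-SD units.
- **Association** — per-variant additive-model OLS (dosage 0/1/2) under two
  covariate models: Model 1 (age, gender, site) and Model 2 (plus fat intake,
  physical activity, BMI, alcohol, smoking, hypertension, diabetes).
- **Risk scores** — dual-significance selection (p < 0.05 in *both* models),
  risk-allele orientation (the allele moving the trait adversely, which may
  be the major allele), and the scores

  uGRS = Σᵢ aᵢ  and  wGRS = Σᵢ wᵢ aᵢ,

  with aᵢ the risk-allele dosage and wᵢ = |β̂ᵢ| from the fully adjusted model,
  followed by score–trait regression.
- **Unit back-transformation** — β·SD in mg/dL for normal traits; the
  geometric fold-change GSD^β for log traits.
- **Interactions** — gender/site-stratified fits and SNP×modifier product-term
  screens (gender, site, obesity = BMI ≥ 25 kg/m², fat intake, physical
  activity).
- **Power** — the noncentral chi-square power of the 1-df additive test,
  λ = n·r²/(1−r²), and its inverse (minimum detectable r²).
- **Synthetic cohort generator** — genotypes under Hardy–Weinberg at the
  published site-specific MAFs, covariates from the published marginals,
  phenotypes from additive effects of the published magnitudes (TG log-normal
  with geometric mean 125.96 mg/dL, geometric SD 1.60), ≥95% call-rate
  missingness — so the full pipeline runs and is testable without the
  access-controlled study genotypes.

## Worked example

```python
import lipidgrs as lg
from lipidgrs.association import prepare_traits
from lipidgrs.scores import build_score_definition

G, cohort, panel = lg.simulate_cohort(seed=11, call_rate=0.98)
retained, qc = lg.qc_filter(G, cohort["site"].to_numpy())
results = lg.run_panel(G, cohort, panel)

definition = build_score_definition(results, "TG", panel_order=list(panel["rsid"]))
wgrs = lg.compute_wgrs(G, definition)
z, _ = prepare_traits(cohort, ("TG",))
fit = lg.grs_association(wgrs, cohort, z["TG"], "TG")
```

Output from this exact run:

```
QC: 12/12 variants retained
TG score variants: rs174546, rs17482753, rs4148005, rs4420638, rs7832643
weights: [0.15, 0.26, 0.09, 0.1, 0.07]
wGRS-TG: beta=0.96, SE=0.15, p=7.33e-11, n=2117
TG geometric mean 126.34 mg/dL, GSD 1.61
fold-change per score unit: 1.58
power at r2=1%: 0.996
```

Reading it: all 12 variants pass call-rate and Hardy–Weinberg filters; five
variants are dual-model significant for TG on this simulated cohort (the
selected set varies with sampling noise for variants near p = 0.05); each
unit of the weighted score raises standardized log-TG by 0.96 SD (the study
reports 0.95 ± 0.16 for its score), i.e. a ×1.58 multiplicative change in TG
per score unit at GSD 1.61; and a variant explaining 1% of trait variance is
detected with 99.6% power at n = 2,117.

The same stages are scriptable via the CLI:

```bash
lipidgrs simulate --n 2117 --seed 11 --out-dir sim/
lipidgrs qc --genotypes sim/genotypes.csv --phenotypes sim/phenotypes.csv --out qc.tsv
lipidgrs associate --genotypes sim/genotypes.csv --phenotypes sim/phenotypes.csv --out assoc.tsv
lipidgrs grs --results assoc.tsv --trait TG --genotypes sim/genotypes.csv \
    --phenotypes sim/phenotypes.csv --out grs.tsv
lipidgrs run --out-dir pipeline_out --seed 11     # whole pipeline + report bundle
```

## Layout

- `src/lipidgrs/reference.py` — embedded published summary tables (panel,
  cohort marginals, association estimates) used as calibration inputs
- `src/lipidgrs/cohort.py` — synthetic-cohort generator
- `src/lipidgrs/qc.py`, `transforms.py`, `association.py`, `scores.py`,
  `interactions.py`, `power.py` — the analysis stages
- `src/lipidgrs/io.py`, `pipeline.py`, `cli.py` — formats, driver, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
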