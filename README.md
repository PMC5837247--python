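# statintol

Pharmacogenetics of statin intolerance from EMR-style records: phenotyping,
dominant-model association, trial interaction, and meta-analysis — with a
seeded synthetic cohort generator so the whole pipeline runs and is tested
without any patient data.

## The scientific problem

Statins are among the most prescribed drugs worldwide, and muscle-related
intolerance (myalgia, CK elevations, switching and discontinuation) is the
main reason patients stop taking them. The common *LILRB5* missense variant
rs12975366 T>C (Asp247Gly, GRCh37 chr19:54759361) is associated with
circulating creatine kinase (CK), making it a candidate susceptibility
marker for muscle symptoms — but also a potential confounder of any
CK-based intolerance definition. This package implements that analysis as a
reusable pipeline for biostatisticians and pharmacoepidemiologists:

1. **Phenotyping** (`statintol.phenotyping`) — classify statin users from
   longitudinal prescriptions and labs into *general statin intolerance*
   (GSI: on-statin CK above the ULN plus ≥2 switches or discontinuation)
   versus tolerant controls (ST1: >90% coverage for ≥5 years at ≥40 mg/day
   simvastatin-equivalent, never switched, CK consistently normal), and the
   CK-independent *low-dose intolerance* (LDI: ≥2 statins with one
   discontinued at its lowest approved starting dose) versus ST2 controls
   (ST1 minus the CK criterion).
2. **Association** (`statintol.association`) — dominant-model contrasts of
   Asp247 homozygotes (T/T = 1) vs Gly carriers (T/C, C/C = 0): crude 2×2
   odds ratios with Woolf CIs, exact Hardy–Weinberg tests, covariate-
   adjusted logistic regression with backwards stepwise elimination
   (genotype forced), the genotype×treatment logistic interaction for trial
   data, and genotype-stratified Cox fits of the treatment hazard ratio.
3. **Meta-analysis** (`statintol.meta_analysis`) — inverse-variance fixed
   effects on per-study log odds ratios, β = ln OR, w = 1/SE², with SE
   reconstructed from printed 95% CIs as (ln U − ln L)/(2·1.959964), plus
   Cochran's Q and a forest table.
4. **Synthetic cohorts** (`statintol.simulate`) — seeded generators that
   plant Hardy–Weinberg genotypes (MAF 0.37), dominant odds ratios (1.96
   GSI, 1.43 LDI), and genotype-stratified trial hazards (0.87 in T/T, 1.23
   in carriers) into EMR-style trajectories that the phenotyping rules
   recover exactly.

See `docs/methods.md` for the full model description and assumptions.

## Worked example

Either run the numbered drivers (`analysis/01_simulate_cohort.py` …
`analysis/05_meta_analysis.py`, writing under `results/`) or the CLI:

```bash
statintol all --seed 1 --out-dir results/run1
```

which simulates a 5000-patient cohort, phenotypes it, fits both
associations and pools the packaged study table. With seed 1 the drivers
print:

```
GSI: {'unclassified': 4612, 'case': 252, 'control': 136}; agreement with planted truth 100.0%
LDI: {'unclassified': 4582, 'case': 248, 'control': 170}; agreement with planted truth 100.0%
GSI adjusted  : OR 2.89 (1.85-4.52) p=2.86e-06 n=388 [planted 1.96]
LDI unadjusted: OR 1.39 (0.93-2.06) p=0.108 n=418 [planted 1.43]
treatment HR in T/T homozygotes: 0.87 (0.68-1.09) p=0.22 [planted 0.87]
treatment HR in Gly carriers: 1.17 (0.99-1.39) p=0.069 [planted 1.23]
pooled (fixed effects)    1.34  1.16-1.54  z=3.97 p=7.1e-05 Q=2.57 I2=0%
```

Reading this: most statin users are unclassifiable by design (only clear-cut
cases and long-term adherent controls qualify); the classifier reproduces
the generator's planted classes exactly; a single 5000-patient replicate
estimates the planted odds ratios with wide CIs (the test suite shows the
estimator is unbiased over 200 replicates); the stratified trial fits
recover the planted treatment-by-genotype pattern (protective in T/T,
harmful in carriers, interaction OR 0.73, p = 0.04 in this run); and
pooling the four per-study adjusted estimates gives OR 1.34 (1.16–1.54),
i.e. Asp247 homozygotes have ~34% higher odds of intolerance-related
outcomes than Gly carriers.

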