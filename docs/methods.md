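# Methods

## Problem and scope

`statintol` implements a pharmacogenetic analysis of statin intolerance
around the common *LILRB5* missense variant rs12975366 T>C (Asp247Gly,
GRCh37 chr19:54759361). The variant is a known determinant of circulating
creatine kinase (CK), which makes CK-dependent definitions of intolerance
potentially confounded; the pipeline therefore carries two EMR-derived
phenotypes — one CK-dependent, one CK-independent — plus a randomized-trial
interaction analysis and a cross-study meta-analysis. Because no individual-
level data can ship with the package, a synthetic cohort generator plants
the assumed statistical structure and every downstream stage is tested
against those planted truths.

## Phenotyping model

Patients enter with at least two statin prescriptions. Each script covers
the half-open interval `[start_date, start_date + days_supply)`; overlapping
scripts are unioned, never double-counted. The per-patient therapy window
runs from the first script start to the earlier of last covered day and the
end of records (the synthetic database closes 2013-07-31).

* **GSI (general statin intolerance) case**: any on-statin CK strictly above
  the sex-specific upper limit of normal (defaults 320 IU/L male, 200 IU/L
  female; laboratory ULNs are assay-specific, so they are configurable), and
  either ≥2 statin switches or discontinuation of all statin therapy.
* **ST1 control**: coverage > 0.90 (strict, "over 90%"), ≥5 years on
  therapy, time-weighted mean dose ≥40 mg/day simvastatin-equivalent, zero
  countable switches, no total discontinuation, and all on-statin CK normal.
* **LDI (low-dose intolerance) case**: ≥2 distinct statins with ≥1
  discontinued at or below its lowest approved daily starting dose,
  irrespective of CK.
* **ST2 control**: all ST1 criteria except the CK one (so ST1 ⊆ ST2).

Conventions that the data cannot decide and are therefore configuration:

* A switch is a drug change between chronologically consecutive scripts;
  simvastatin→atorvastatin changes on/after 2012-05-01 (UK atorvastatin
  patent expiry) are treated as systemic formulary shifts and not counted.
  Whether the GSI rule counts switch events or distinct statins is
  ambiguous in principle; the default counts switch events
  (`gsi_switch_metric`).
* A course is discontinued when no same-drug script starts within 90 days
  (strict >) after coverage ends and the course is not ongoing at the end
  of records. "Discontinued therapy" for GSI means no statin of any kind
  after the gap; the LDI rule is per-drug, matching its per-statin wording.
* The dose criterion uses the time-weighted mean simvastatin-equivalent
  dose (dispensed-days weighting); a minimum-maintained-dose alternative is
  available (`dose_summary`).
* Dose equivalence uses a standard potency ladder (simvastatin 40 ≈
  atorvastatin 20 ≈ rosuvastatin 10 ≈ pravastatin 80 ≈ fluvastatin 80 ≈
  lovastatin 80 ≈ pitavastatin 4); lowest approved starting doses are the
  NLA 2014 values (10/10/5/40/20/20/2 mg/day). Both tables are overridable.
* Same-day scripts of different drugs are ordered by drug name; both
  contribute coverage and the transition counts once. Case rules take
  precedence over control rules, so a patient is never case and control of
  the same phenotype.
* On-statin CK flags are tri-state: with no on-statin CK at all they are
  undetermined and the patient cannot be an ST1 control. The
  myopathy-candidate flag uses an inclusive ≥4×ULN; "above ULN" is strict.

## Association model

All genetic contrasts are dominant: Asp247 homozygotes (T/T, coded 1)
versus Gly carriers (T/C or C/C, coded 0). Crude 2×2 odds ratios use the
Woolf interval, `SE = sqrt(1/a+1/b+1/c+1/d)`, with the Haldane–Anscombe 0.5
correction applied (and logged) only when exactly one cell is zero; a zero
margin is an error. Adjusted models are maximum-likelihood logistic fits
(statsmodels) with Wald standard errors and p-values — Wald rather than LRT
to match conventional SAS-style logistic output, with an LRT helper as
secondary. CK enters as log10(CK) (natural log switchable at call sites).
95% intervals use z = 1.959964; displayed values are rounded half-up to two
decimals.

Backwards stepwise elimination drops, one per iteration, the non-forced
term with the largest Wald p-value above α (default 0.05, not dictated by
the design; flagged in reports), refitting each time; the genotype term is
always forced, and multi-column blocks are removed on their joint Wald
chi-square. The removal order (largest p first) makes the procedure
deterministic given the table. The orchestration layer screens out
constant or all-missing covariates before fitting, since they cannot be
identified.

For trial data, the interaction analysis is the logistic model
`myalgia ~ genotype + arm + log10(final CK) + genotype×arm`, and the
stratified analysis fits a Cox proportional-hazards model of the treatment
arm within each genotype stratum, adjusted for log10 final CK (lifelines).
Both routes are provided because the source tables mix odds-ratio and
hazard-ratio presentations of the same contrast.

## Meta-analysis

Fixed effects only: per-study `beta = ln(OR)` with SE reconstructed from
the printed 95% CI as `(ln U − ln L)/(2·1.959964)`; the point estimate is
taken from the printed OR, the CI supplies only the SE (standard practice;
the alternative CI-midpoint reconstruction does not reproduce the published
pooled value). Pooling uses `w = 1/SE²`, pooled `SE = 1/sqrt(Σw)`, a
two-sided z-test, and Cochran's Q with I² reported descriptively. A
reconstruction warning fires when the point estimate is >2% from the
geometric centre of its CI. The packaged study table uses the four
*adjusted* per-study estimates — 1.43 (1.10–1.86), 1.03 (0.72–1.49),
1.48 (1.05–2.10), 1.35 (1.07–1.71) — because inverse-variance recomputation
with that set uniquely reproduces the published pooled 1.34 (1.16–1.54);
this input-set choice is an inference, not a documented fact.

## Synthetic data generator

The generator emulates the *structure* the analysis assumes, not any real
cohort's descriptive statistics. Covariates are independent (the real
covariate correlation structure is unpublished): age ~ Normal(60, 10)
truncated to [35, 90]; sex 50/50; type-2 diabetes 0.85; interacting
co-medication 0.47. Genotypes are Hardy–Weinberg at MAF 0.37
(observational) or 0.40 (trial).

The latent class (GSI case, LDI case, tolerant, other) is drawn from
per-patient category probabilities in which each case class is proportional
to `OR^d · exp(x'γ)` and the tolerant probability is constant. Ratios of
category probabilities are unaffected by the remainder class, so the
conditional case-vs-control log-odds is exactly linear with slope `ln(OR)`
on the dominant code — the planted OR is the logistic estimand (a logistic,
not probit, liability for exactly this reason) and recovery is unbiased
without collider corrections. Planted defaults: OR 1.96 (GSI), 1.43 (LDI),
each case class at 5% prevalence, tolerant fraction 0.037 of users, with
20% of tolerant patients carrying an incidental CK elevation (ST2-only), so
ST2 membership exceeds ST1 as in the source populations. Covariate effects
(co-medication ln 1.5 on both phenotypes, female ln 1.33 and −ln 0.85 per
age decade on GSI) are plausible EMR-scale associations.

Trajectories are noise-free by construction so that classification is
exact: tolerant patients tile 56-day simvastatin or atorvastatin scripts
(40/80 mg simvastatin-equivalent) with gaps ≤4 days from therapy start to
the records end; GSI cases run three consecutive statin courses (two
countable switches, every discontinued dose above its lowest starting
dose) and stop, with one CK spike at `ck_uln_multiplier_cases`×ULN
(default 2); LDI cases discontinue a lowest-starting-dose course and later
start a second statin, CK normal; the unclassifiable remainder has a short
single-statin course. Drug and dose mixes overlap between classes so that
first-statin and dose covariates are informative but not separating.
Normal CK values are log-normal with sex-specific medians (100/70 IU/L,
σ ≈ 0.18 log10) clipped below 0.95×ULN — the clip guarantees noise-free
class recovery and is the main idealisation. Because records are
noise-free, the 100%-agreement tests validate the rule logic, not
robustness to real EMR noise (miscoded scripts, missing labs, partial
adherence), which the generator deliberately does not model. No linkage
disequilibrium and no multi-variant structure are simulated.

The trial generator randomizes exactly half of participants to treatment
(permuted, independent of genotype), draws exponential event times with
rate `baseline_myalgia_rate × HR_stratum^treated` (planted HRs 0.87 in T/T,
1.23 in carriers), and censors administratively at Uniform(median−0.4,
median+0.4) years, median 1.9. The default baseline rate 0.0505 events per
person-year solves the expected-event-fraction equation so the overall
myalgia fraction is 837/8749 ≈ 0.096 at n = 8749, MAF 0.40. Final CK is
log-normal and depends on genotype only (T/T shifted +0.06 log10, matching
the variant's CK association) — deliberately independent of the outcome so
that adjusting for it cannot bias the treatment effect.

## Numerical choices and problem sizes

* Exact Hardy–Weinberg test: conditional enumeration over heterozygote
  counts in log space (gammaln), summing configurations with probability
  ≤ the observed (1 + 1e−12 tolerance against ties lost to rounding).
* Logistic fits fail loudly on single-class outcomes, rank-deficient
  designs (collinear columns listed) and complete single-term separation.
* Dates are ISO-8601; coverage arithmetic is integer-day.
* Recovery suites use 200 replicates at n = 5000 (observational) and
  n = 8749 (trial), sizes at which Monte-Carlo error of the mean log-effect
  is ≈0.01–0.02, comfortably inside the ±0.1 recovery bands; smaller
  shared fixtures (n = 1500–4000) back the unit-level round-trip tests.

## Known limitations

* The phenotyping thresholds (ULN, equivalence and lowest-dose tables,
  patent date) are field-standard defaults, not values published with the
  source analyses; all live in `RulesConfig`.
* The generator's noise-free trajectories overstate classifier performance
  relative to real EMRs by design (see above).
* The crude 2×2 OR for the adjudicated-myopathy table (1.215, Woolf CI
  0.876–1.685) intentionally differs from the published centre-adjusted
  1.48 (1.05–2.10); the per-centre breakdown needed to reproduce the
  adjusted value is not public.
* Only a single biallelic variant is handled; no genome-wide scanning,
  imputation, or multi-variant risk scores.
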