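# Methods

## Scoring model

The package implements P-value-threshold polygenic scoring without LD
clumping.  For trait weights `w_j` (always stored on the log-odds / linear
"beta" scale; odds-ratio input columns are log-transformed exactly once, at
ingest) and effect-allele dosages `d_ij`, the raw score is the plain
weighted sum `Σ_j w_j d_ij` over variants with GWAS P strictly below the
threshold.  There is no per-SNP averaging and no clumping or pruning step:
the scoring model treats variants as independent, which is a deliberate and
documented deviation from common C+T practice — it matches the additive
formula used downstream and is what makes the synthetic calibration
(below) closed-form.  Users with LD-structured data should clump upstream.

Thresholding uses strict `<` (the grid notation is "P_T < x"), so P-values
sitting exactly on a threshold, including P = 1, are excluded.  The default
grid is {0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1}.

Missing dosages are mean-imputed per variant by default, which keeps the
score scale comparable across samples with different missingness; `zero`
and `exclude` policies are switchable.  Standardization maps raw scores to
mean 0 / SD 1 with the sample SD (ddof = 1) over the combined cohort —
cases and reference together, per trait and per threshold.  With a small
case fraction this approximates reference-centred scoring (the combined SD
is inflated by the factor sqrt(1 + p(1−p)δ²) ≈ 1.005 at p = 22/329 and
δ = 0.41); reference-only centring is available via `reference_mask`.
Standardization is idempotent and affine-invariant, and constant scores
are a hard error rather than a silent zero-division.

## QC and harmonization

Variant filters keep MAF > 0.01 AND INFO > 0.9, both strict inequalities,
so boundary values are removed.  Sample call rates below 95% are flagged
but never removed automatically — the policy of the study design this
emulates, where a flagged sample showed no other anomaly and was retained;
removal is an explicit separate call.  MAF is computed from the combined
cohort's non-missing dosages.

Harmonization joins summary statistics to genotypes by variant ID (the
synthetic writer guarantees unique IDs; real data should be deduplicated at
ingest, which the reader does).  When the effect allele is the VCF ALT the
dosage is used as-is; when it is REF the dosage becomes `2 − d`, leaving
published weights untouched so reported effect sizes remain recognizable.
A/T and C/G pairs are strand-ambiguous and dropped by default (an override
exists for data with known strand); allele pairs matching neither
orientation are dropped and counted.  All drop/flip counts are returned in
a report and logged.

## Association layers

* **t-test** — pooled-variance two-sample t on standardized scores
  (Welch by flag); δ = mean(cases) − mean(reference).
* **Logistic OR per SD** — maximum-likelihood fit of case status on the
  standardized score with intercept; OR = exp(β̂), CI = exp(β̂ ± 1.96·SE),
  two-sided Wald P.  Wald construction was chosen as the standard
  single-covariate default.  No covariates enter the model.  Complete
  separation and non-convergence produce a flagged status with NaN
  interval, never a fabricated CI.
* **Symptom ANOVA** — per symptom, one-way ANOVA of score by yes/no status
  (for two levels F = t² exactly, which the tests verify).  Missing symptom
  responses are excluded pairwise; a single-level symptom is returned as
  `untestable`.  No multiple-testing correction by default, because the
  follow-up symptoms within a domain are strongly dependent and the layer
  is interpreted at a nominal 0.05; Bonferroni is available but off.
* **Prevalence summary** — counts and percentages per symptom with the
  non-missing denominator, flagged when the denominator falls short of the
  cohort size (a printed 33.3% for 6 positives out of 19 subjects implies
  18 respondents — exactly the situation the flag surfaces).

## Synthetic generator

The generator emulates the study design end to end and is the package's
test bed; its defaults are the study conditions, chosen once:

| parameter | default | meaning |
|---|---|---|
| n_cases / n_controls | 22 / 307 | case series vs population reference |
| delta_target | 0.41 | standardized case score shift, SD units |
| n_snps | 2000 | desk-scale variant panel |
| n_gwas | 50,000 | effective discovery-GWAS size for SE/P generation |
| causal_fraction | 0.1 | fraction of variants with nonzero true effect |
| effect_sd | 0.05 | SD of causal per-allele log-odds effects |
| maf_range | (0.05, 0.5) | uniform effect-allele frequency range |
| missing_rate | 0.01 | per-genotype missingness |

n_snps, causal_fraction and effect_sd are plumbing scale choices: 2000
variants keep every simulation fast while leaving tens to hundreds of
variants in each threshold bin; 10% causal with SD 0.05 gives summary
statistics a realistic polygenic tail (most P-values null-like, a minority
strongly associated).  n_gwas = 50,000 is typical of the mid-2010s
discovery GWAS the weights would come from.  INFO scores are drawn
Uniform(0.5, 1] so the INFO > 0.9 filter genuinely bisects the panel, and
roughly 30% of variants are written with REF = effect allele so
harmonization flips are exercised on every run.

**Summary statistics.**  True effects are Normal(0, effect_sd²) for a
causal_fraction of variants, zero otherwise; the reported effect adds
Normal(0, se²) noise with `se = 1/sqrt(2 f (1−f) n_gwas)` — the standard
error of a marginal regression on an additive genotype — and the reported
P is the two-sided normal tail of effect/se.  With causal_fraction = 0 the
P-values are exactly Uniform(0, 1) in distribution.

**Calibration.**  Case enrichment is realized retrospectively by tilting
allele frequencies at score variants: `f'_j = clip(f_j + λ w_j f_j(1−f_j),
ε, 1−ε)` with ε = 1e−4.  Under independent Binomial(2, f) genotypes the
expected raw-score gap is `λ · 2 Σ w_j² f_j(1−f_j)` and the raw-score SD
is `sqrt(2 Σ w_j² f_j(1−f_j))`, so

    λ = delta_target / sqrt(2 Σ_j w_j² f_j (1−f_j))

makes the expected standardized gap equal delta_target exactly (before
clipping; clip events are counted and surfaced).  The recovery tests run
500 genotype replicates at n_snps = 500 and confirm the observed mean δ
within ±0.05 for targets 0.2, 0.41 and 0.58.  Note the calibration is
specific to the variant set it was solved on: applying QC filters or a
different threshold downstream retains only part of the tilted weight
variance and dilutes the realized δ by sqrt of the retained fraction —
visible, and expected, in full-pipeline runs.

A score-level shortcut (`simulate_score_cohort`: reference ~ N(0,1), cases
~ N(δ,1)) tests the association layer in isolation; with equal unit
variances the population logistic slope equals the mean gap δ (normal
discriminant identity), so OR per SD ≈ exp(δ): δ = 0.41 ↔ OR ≈ 1.5,
δ = 0.58 ↔ OR ≈ 1.85.  At 22 cases the ML slope carries a small upward
finite-sample bias and the replicate mean of exp(β̂) adds Jensen inflation,
so replicate means run a few percent above exp(δ).

**Follow-up phenotypes.**  Symptom j of subject i is Bernoulli with
probability `logistic(logit(base_rate_j) + effect_j · score_i)`.  Default
base rates are the observed six-year prevalences of the 12 canonical
symptoms in a 19-subject cohort (e.g. nightly coughing 5/19 ≈ 26.3%,
topical steroids 6/19 ≈ 31.6%); default effects put +1 log-odds per SD on
the five asthma-domain symptoms and 0 elsewhere, mirroring the observed
pattern of asthma-symptom-positive subjects carrying higher scores.

**What the generator does not model:** linkage disequilibrium, population
stratification and ancestry mismatch between cases and reference,
Hardy-Weinberg violations, imputation error structure (INFO scores are
decorative draws, not a quality model), genotyping batch effects, and
reference sets that are screen-positive for the traits studied.  Passing
tests on this generator therefore demonstrate the pipeline's arithmetic
and statistical machinery, not robustness to those real-data phenomena.

## Numerical and design choices

* Coordinates are 1-based as in VCF; variants key on ID with summary-stat
  files deduplicated (first occurrence kept, counted).
* Reported P-values are clipped to (tiny, 1] so the (0, 1] contract holds
  under extreme z-scores.
* Problem sizes in the test suite (500-replicate calibrations at 500
  SNPs, 1000-replicate null calibration, 2000-replicate OR recovery in the
  acceptance script, 10⁵-per-group discriminant-limit check) were chosen
  to pin each Monte-Carlo estimate well inside its assertion tolerance
  while keeping any single test under a minute on one CPU.
* Determinism: every generator routine is a pure function of (inputs,
  seed) using `numpy.random.default_rng`; pipeline reruns on identical
  inputs produce byte-identical tables, and the log format contains no
  timestamps for that reason.
* The pipeline labels cases by sample-ID prefix (default `case`), a
  convention the synthetic writer follows; real cohorts can be renamed at
  VCF generation or supply their own labels through the library API.

## Known limitations

No LD-aware scoring or shrinkage estimators; no BGEN/PLINK binary inputs;
no covariate adjustment in the logistic layer (by design — none is used in
the emulated analysis); Wald intervals are poor under separation-adjacent
sparsity, which is flagged rather than repaired (a profile-likelihood or
Firth option would be the natural extension).
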