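# Methods

This note records the models, conventions, and numerical choices behind
`pgseval`, and what the synthetic cohort does and does not establish
about real data.

## Scoring and harmonization

A polygenic score is `PGS_j = Σ_i w_i · d*_ij` over the harmonized
variants of one scoring file, where `d*_ij` is the orientation-resolved
effect-allele dosage. Harmonization matches scoring-file records to
genotype records by **(chromosome, position)** with allele
reconciliation, not by rsID: position matching is robust to identifier
drift across dbSNP builds, and rsID-to-position resolution against
external databases is out of scope. For each record the alleles are
compared to the cohort's ref/alt pair as written (*direct* match) and
after strand complementation (*flip* match); the orientation flag records
whether the effect allele is ALT (score the ALT dosage `d`) or REF
(score `2 − d`). Strand-ambiguous pairs (A/T, C/G) cannot be assigned a
strand from the alleles alone and are **dropped by default** — the
conservative standard — with a `keep` policy available that reads them
as written. Irreconcilable alleles count as mismatches; ungenotyped
positions as absent. The five counts partition the score's variants, and
coverage = matched/total. Multi-allelic VCF records are excluded at load
(keeps dosage semantics unambiguous), and variants with imputation
quality `Rsq < 0.6` are excluded by default; a missing Rsq field passes
(fully imputed panels always carry it; plain genotyped fixtures need not).

Missing dosages are mean-imputed per variant by default, which keeps
scores comparable across samples with unequal missingness; an `omit`
policy drops the term instead. A variant missing in every sample then
contributes a constant and leaves standardized scores unchanged.

## Conventions that downstream numbers depend on

- **Standardization** uses the sample (n−1) SD over a declared reference
  set (default: the full cohort). Any odds-ratio-per-SD statement
  inherits this convention.
- **Percentiles** are empirical `rank/n` with ties sharing their
  *maximum* rank, computed over the full cohort (cases + controls);
  "above the q-th percentile" means `percentile > q` strictly. A
  controls-only reference can be had by passing a reference subset.
  Consequence of max-rank ties: a tie block straddling the cut moves
  entirely *above* it, so the high-score group can exceed a `1−q`
  fraction; with distinct scores it is exactly `floor((1−q)·n)`.
- **Two-sided Fisher** uses the probability-mass rule (sum of
  hypergeometric probabilities ≤ that of the observed table); the
  statistic is the sample cross-product ratio ad/bc.
- **Kolmogorov–Smirnov** uses the exact null when `n_a·n_b ≤ 10,000`
  and the asymptotic Kolmogorov distribution otherwise. **Mann–Whitney**
  uses the two-sided normal approximation with midrank ties and
  continuity correction throughout — at cohort sizes where these tests
  are interesting, exact enumeration adds nothing.
- **Percentile OR CIs** are Wald on the log-odds scale,
  `exp(β ± 1.96·SE)`, hence asymmetric on the OR scale. Complete
  separation of the threshold indicator (an empty cell in the implied
  2×2) is detected before fitting and reported as non-estimable with a
  direction, never as a fitted number. Missing covariates are handled
  complete-case per fit, with the analyzed n reported.
- The **correlation screen** encodes binary covariates 0/1 and smoking
  on the ordered scale no=0, former=1, yes=2 (an explicit ordinal
  choice; a one-hot screen can be run by passing the dummy columns as
  covariates). The flag threshold `|r| > 0.75` is strict.

## Predictive-model protocol

The suite mirrors a common clinical-risk workflow: a deterministic
stratified 80/20 split (case/control proportions preserved within one
sample), logistic models fitted by maximum likelihood (Newton scoring,
i.e. IRLS; convergence tolerance 1e-10, 100 iterations), and three
models per score — covariates-only, PGS-only, combined. The 10-fold CV
repeated 10 times runs on the training side only, as an internal sanity
check whose mean AUC is logged; headline AUCs come from the held-out
20%, and the covariates-only vs combined comparison uses DeLong's paired
test on those shared test samples, where it is valid.

AUC is computed by the Mann–Whitney formulation (probability that a
random case outscores a random control, half-credit ties) via midranks;
its variance is DeLong's placement-value estimator, and the paired test
builds the 2×2 covariance of the two AUCs from per-sample placement
values, `z = Δ/√(v_a + v_b − 2c)`. Identical scores (zero variance of
the difference) return z = 0, p = 1 by convention. A single-feature
logistic model is a monotone transform of its feature, so the PGS-only
model's test AUC equals the raw score's AUC — a property the tests
exploit as an oracle.

Boruta runs for a fixed number of iterations (default 50); each
iteration appends a row-shuffled shadow copy of every candidate feature,
fits a 200-tree random forest (depth cap 5), and records a hit for each
real feature whose importance exceeds the best shadow importance.
Decisions are two-sided binomial tests against Binomial(n, ½) with Holm
step-down at α = 0.05: significantly many hits confirms, significantly
few rejects, anything else stays tentative (a legal outcome). The
importance measure is the forest's impurity-based importance — the
standard practice in Python Boruta implementations and ~100× cheaper
than refitted permutation importance at these sizes; the decision
procedure is unaffected. If Boruta confirms nothing, the suite falls
back to the full covariate list with a warning rather than fitting an
empty model.

Stratified analyses report raw p-values by default (the matrices are
descriptive); Bonferroni and Benjamini–Hochberg switches add a clearly
labelled adjusted column. Groups below 2 per side are skipped with a
warning — small strata (e.g. a 68-sample island subgroup) are reported
with their honestly wide CIs rather than suppressed.

## The synthetic cohort

`simulate_genotypes` draws, per variant, an ancestral frequency
`p ~ U(0.05, 0.95)` and per area a frequency from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` — the Balding–Nichols model, the minimal
standard divergence model — then Hardy–Weinberg `Binomial(2, p_area)`
genotypes. Defaults define the study conditions: four areas of sizes
2030/420/744/68, per-area divergence 0.002–0.015 (small within-peninsula
differentiation, a more diverged island), 1000 independent variants, 20%
causal with N(0,1) weights. Substitutions are transition-biased (70%),
so ~15% of sites are strand-ambiguous, and causal variants sit only on
unambiguous sites so the true score is exactly representable by a
scoring file under the drop policy.

Disease follows a logistic liability:
`logit P(case) = β₀ + log(OR_sd)·z_true + Σ β_c (c − mean c)`, with
`z_true` the standardized true score. The default `OR_sd = 2` places
score-alone AUCs in the 0.6–0.7 range typical of published
cardiovascular scores (no real effect-size scale is available to copy;
this is a documented choice). Covariates are drawn from distributions
loosely shaped like an early-onset MI cohort (age 40 ± 4.9, BMI 26 ±
3.8, ~88% male, comorbidities logit-linked to age and BMI) — they are
scaffolding for exercising adjustment code, not claims about any
population. Cases and controls are then sampled to a 50% case fraction
(both emulated studies are balanced case-control designs); with the
default β₀ = 0 the population prevalence is already ≈ 50%, so the
emitted cohort is essentially a random subset and logistic coefficients
estimate the generative ones without selection distortion. An
unattainable case fraction raises with advice to adjust β₀.

Scoring-file emission targets a coverage per file (defaults shaped like
real catalog scores: 27 variants at 81.5%, 164 at 77.4%, up through
99.5%), samples matched rows causal-first so every file carries signal,
perturbs weights with N(0, 0.05) noise, strand-complements a fraction of
rows, and plants a few irreconcilable-allele rows — so harmonization's
direct/flip/mismatch/absent paths are all exercised by every fixture.
The drift-confounded score (`simulate_structure_score`) selects the
most frequency-divergent *null* variants between two areas and aligns
unit weights with the divergence sign: a score with zero disease signal
whose distribution nevertheless differs between subgroups, reproducing
the qualitative structure phenomenon deterministically.

**What the generator does not emulate:** linkage disequilibrium
(variants are independent, so LD-aware weighting methods cannot be
studied), genotyping/imputation error beyond the Rsq decoys, covariate
distributions that differ by area, local ancestry, and real catalog
weight scales. Passing tests therefore demonstrate correctness of the
statistical machinery and the qualitative structure/transferability
phenomena — not calibrated performance claims for any real cohort.

## Numerical and degenerate-input choices

- All randomness flows from one integer seed through named
  `SeedSequence` streams (genotypes, phenotypes, scoring files, VCF
  decoys), so every artifact is reproducible and sub-stages are
  independently stable under changes elsewhere.
- Logistic fits that hit a singular Hessian (perfect separation) fall
  back to BFGS and are flagged (`|β| > 30` heuristic) rather than
  raised; constant columns and rank deficiency raise with the offending
  column names.
- Beta draws for area frequencies are clipped to [1e-6, 1−1e-6] to keep
  binomial sampling defined at extreme divergence.
- Empty harmonization results are an error at scoring time (a score over
  zero variants is undefined) but a logged skip at pipeline level, so one
  unmatched file does not abort a batch.
- Zero-variance inputs: standardization raises; the correlation screen
  reports `r = NaN` for that covariate; Boruta rejects the feature.

## Problem sizes in the checks

The calibration checks use 1000 null replicates for test sizes (KS at
n = 200 per group, Mann–Whitney at 60, DeLong at 150 cases/150
controls) and CI coverage (percentile OR at n = 2000), 200 replicates of
n ≈ 4600 for log-OR-per-SD recovery, 20,000 per group for the binormal
AUC limit, and 40 replicates of 500 per area for the structure
phenomenon — sizes at which the binomial 99% acceptance bands are
informative while the whole suite stays desk-scale.
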