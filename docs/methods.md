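# Methods

`migwas` re-implements, as a tested library plus analysis scripts, the
post-GWAS computations of a large migraine case-control meta-analysis:
cohort harmonization and quality control, fixed-effect pooling with an
effective-sample-size precision control, algorithmic risk-locus definition,
summary-statistic stepwise conditional analysis, a four-model Bayesian
classifier for subtype specificity of risk alleles, and two auxiliary
statistics (tissue eQTL enrichment by leave-one-out prediction intervals,
liability-scale heritability conversion). The consortium data behind the
original analysis are access-controlled, so a first-class synthetic-data
generator supplies inputs with the same structure and known ground truth.

## Meta-analysis model

Each cohort provides per-variant log-odds estimates b with standard error
se from a logistic GWAS. The pooled estimate is the inverse-variance
weighted (IVW) fixed-effect combination

    beta = sum(w_i b_i) / sum(w_i),   se = (sum w_i)^(-1/2),   w_i = 1/se_i^2,

with z = beta/se and a two-sided normal p-value computed in log space so
that extreme associations do not round to zero (the table carries both `P`,
clipped at the smallest subnormal double, and `MLOG10P`). Variants present
in only one cohort are kept — the precision control is the effective sample
size, not a cohort-count rule. No heterogeneity statistics are computed.

The effective sample size of a variant is

    N_eff = 1 / (f (1 - f) se^2),

where f is the pooled (weight-averaged) effect-allele frequency. For a
cohort of N samples with case proportion t and imputation info I this
approximates 2 N t (1 - t) I. Variants with N_eff < 5,000 are removed.
Which EAF enters N_eff (pooled vs per-cohort) is an interpretation; the
pooled weight-averaged EAF is used.

Genomic inflation is the standard median-based factor
lambda_GC = median(chi^2) / qchisq(0.5, 1), computed on the
N_eff-filtered set.

## Quality control

Cohorts are harmonized to a reference panel by (chromosome, position,
alleles) after uppercasing and recoding indel alleles to I (longer) /
D (shorter). Where effect/other alleles are swapped relative to the
reference, beta is negated and EAF replaced by 1 - EAF; positions carrying
more than one allele pair are dropped as multiallelic. Exclusion rules:
MAF > 0.01, imputation info > 0.6, HWE p > 1e-6 and missingness < 0.05
(the latter two only when the columns exist), and |EAF - reference EAF|
<= 0.30 for SNPs / 0.20 for indels. The EAF discrepancy is computed after
allele harmonization — computing it before would count every allele swap
as a discrepancy. Each excluded variant is attributed to the first failing
rule in the fixed order multiallelic → match failure → MAF → info → HWE →
missingness → EAF discrepancy; the order is a reporting convention, not a
statistical choice, and is needed for a well-defined exclusion table.

Strand-ambiguous SNPs (A/T, G/C) are audited, not filtered: for a cohort
pair, the proportion of shared ambiguous SNPs whose minor allele is the
same allele in both tables is reported per MAF stratum. Near-perfect
concordance at low MAF indicates consistent strand labelling; at MAF near
0.5 the minor allele is genuinely ambiguous and concordance drops without
implying a strand problem.

## Risk loci

Given genome-wide significant (GWS, p < 5e-8) variants and a reference LD
panel of signed correlations r:

1. **Index variants** — greedy P-ordered clumping: repeatedly take the
   remaining GWS variant with the smallest p and discard all GWS variants
   with r^2 > 0.1 to it. Variants with unknown reference LD are resolved
   against an optional secondary panel (absorbed when in LD with an index;
   replacing that index when their p is smaller) and otherwise promoted to
   singleton index candidates. P-value ties are broken by (chromosome,
   position, alleles) for determinism.
2. **Blocks and merging** — each index spans the interval of all GWS
   variants with r^2 > 0.6 to it (an index with no partner yields a 1-bp
   locus); same-chromosome intervals separated by less than 250 kb
   (end-to-start) merge.
3. **Assignment and final merge** — every remaining GWS variant joins its
   nearest locus by boundary distance (ties to the lower-coordinate locus;
   distances measured to the boundary, not the lead), boundaries update,
   and a final merge pass runs. Merging never crosses chromosomes.

The lead variant is the minimum-p member. A locus is named after the
nearest protein-coding gene to the lead, or the nearest noncoding gene if
no protein-coding gene lies within 250 kb, with "Near" prefixed when the
lead does not overlap any transcript; with no gene available the name
falls back to `chr:pos`. Gene annotation is read from BED (0-based
half-open, converted to 1-based inclusive) with name and biotype columns.

## Stepwise conditional analysis

Per locus, candidates are SNP members (indels excluded) with N_eff within
±10% of the lead's — summary statistics from a meta-analysis with widely
varying per-variant sample sizes otherwise produce spurious conditional
p-values. Starting from the lead (or, when the lead fails the window, the
strongest candidate in LD r^2 > 0.3 with it), each remaining candidate's
z-score is conditioned on the selected set s via the panel correlations R:

    z_c|s = (z_c - R_cs R_ss^{-1} z_s) / sqrt(1 - R_cs R_ss^{-1} R_sc),

and the minimum-p candidate is added while its conditional p < 5e-8. This
is summary-statistic joint regression (the COJO-style conditioning
mathematics); z = beta/se is used directly, justified by the N_eff
homogeneity inside the window. Numerical guards: candidates with
r^2 > 0.95 to any selected variant, or with conditional variance below
1e-8, are dropped and logged; the conditional variance is asserted to be
at most 1 for a PSD panel; at most 10 steps are taken per locus.

## Subtype classifier

For a variant with paired subtype estimates (b_MO, b_MA) and standard
errors (se_MO, se_MA), the sampling covariance is

    Sigma = [[se_MO^2, c se_MO se_MA], [c se_MO se_MA, se_MA^2]],

where c is the estimator correlation induced by shared controls,
estimated as the empirical Pearson correlation of effect estimates over
common (MAF > 0.05) variants without strong association in either subtype
(p > 1e-4); a minimum of 100 qualifying variants is required. Four
generating models are compared through their marginal likelihoods — the
bivariate normal density of the estimates at mean zero with covariance
Sigma + P_m:

| model | prior effect covariance P_m |
|---|---|
| NULL | 0 |
| MO | diag(tau^2, 0) |
| MA | diag(0, tau^2) |
| BOTH | ½ tau^2 [[1,1],[1,1]] (fixed) + ½ tau^2 I (independent), as a mixture |

with tau = 0.2 on the log-odds scale and equal prior model weights.
Posteriors follow from Bayes' rule; all densities are evaluated in log
space with log-sum-exp for the BOTH mixture because standard errors span
orders of magnitude. A variant is labelled when one model exceeds 95%
posterior probability, otherwise "unresolved"; NULL above 95% is reported
as NULL (the original figure grays such points, so this is a reporting
extension, not a model change).

A companion test checks effect equality with
z = (b_MO - b_MA)/sqrt(se_MO^2 + se_MA^2 - 2 c se_MO se_MA) at the
Bonferroni level 0.05/123; c defaults to the estimated 0.148 ("accounting
for the correlation"). The variance of the difference,
(se_MO - se_MA)^2 + 2 se_MO se_MA (1 - c), is strictly positive for
|c| < 1; the degenerate-variance guard can only fire at c = 1 with equal
standard errors. Direction-concordance questions use an exact two-sided
binomial test at proportion ½ (p = min(1, 2·min(tail probabilities)));
pairs with a zero effect are dropped.

**Resolution limit.** The Bayes factor in favour of an exactly-zero
coordinate against a N(0, tau^2) effect is bounded by
sqrt(se^2 + tau^2)/se (the Savage-Dickey ratio at z = 0). At se = tau/10
this cap is ~10.05, so P(NULL) cannot exceed ~0.81 and P(MO) or P(MA)
saturate near 0.95 no matter how clean the data: certainty above 95% for
those labels requires se << tau (roughly se < tau/100). The classifier's
argmax recovers the generating model reliably at se = tau/10 (>= 90% per
class in the test suite) and labels that are assigned at 95% are almost
always correct, but full-coverage 95%-threshold labelling at that noise
level is mathematically unattainable — a property of the model comparison
itself, documented here because the test suite exercises it explicitly.

## Enrichment and liability scale

*Tissue eQTL enrichment*: per tissue, ordinary least squares of the
observed lead-variant cis-eQTL count on the tissue's total eQTL-gene count
is fitted on all other tissues, and the held-out tissue is compared with
the t-based 95% prediction interval (n-2 degrees of freedom, the
`predict.lm` interval restated): above → "enriched", below → "depleted".
At least 3 tissues are required; a constant predictor in a leave-one-out
subset is an error naming the tissue. The fit uses statsmodels OLS; tests
cross-check fits and intervals against a from-scratch implementation of
the textbook formulas.

*Liability conversion*: with population prevalence K and sample case
proportion P, the observed-scale SNP heritability converts as

    h2_liability = h2_obs * K^2 (1-K)^2 / (P (1-P) z^2),

z the standard normal density at the threshold Phi^{-1}(1-K). The study
constants are K = 0.16 and P = 0.117 = 102,084/(102,084 + 771,257),
giving a conversion factor of 2.9534. Alternative transformations in the
literature give systematically different (higher) liability estimates;
only this formula is implemented.

## Synthetic-data generator

The generator emulates what the pipeline assumes about real consortium
summary statistics; its defaults are the study conditions where stated and
scientifically conventional choices otherwise.

* **LD**: variants partition into blocks; within a block the signed
  correlation is AR(1), r(i,j) = rho^|i-j| (default rho = 0.6, blocks of
  ~20), zero across blocks. AR(1) is the simplest positive-definite
  structure consistent with block LD; real LD from a biobank panel has no
  closed form. Panel sizes beyond dense storage are handled by using the
  implicit block structure directly.
* **Effects**: spike-and-slab — each variant is causal with probability
  0.01, causal log-odds effects are N(0, 0.05^2). Default cohort sizes are
  the five study collections' printed counts (102,084 cases and 771,257
  controls in total); the default panel is 2,000 variants (the study's
  10.8M autosomal variants are far beyond desk scale, and nothing in the
  algorithms depends on the panel size).
* **Noise**: per cohort, se is set from the N_eff identity
  1/(f(1-f) se^2) = 2 N t (1-t) I with per-variant info drawn uniformly
  (default 0.7-1.0); estimates are Gaussian around the LD-induced marginal
  mean (z-mean = R z_joint) with correlation equal to the reference r —
  the standard GWAS result, and what makes the conditional-analysis oracle
  exact. Emitted EAFs carry small Gaussian perturbations around the true
  frequency.
* **QC fodder**: 1% of strand-ambiguous SNPs per cohort are emitted
  allele-flipped (EAF → 1 - EAF, beta → -beta), exercising the
  concordance audit and the EAF-discrepancy rule.
* **Subtype pairs**: labels drawn from a four-vector over
  (NULL, MO, MA, BOTH) (default uniform), nonzero effects N(0, tau^2) with
  tau = 0.2, BOTH half fixed-effect / half independent; estimates drawn
  with estimator correlation c = 0.148.
* **Determinism**: a single seed drives a spawned `SeedSequence`
  hierarchy; identical configs give byte-identical outputs, and no global
  random state is touched.

What the generator does *not* emulate — and therefore what passing tests
do not show about real data: realistic MAF/LD joint structure (real LD
decays with distance and varies with frequency), confounding such as
population stratification (the generator is unconfounded, so lambda_GC
calibration tests only the statistics, not bias correction), per-variant
sample-size distributions of a real meta-analysis (the distribution is a
config choice, since the study does not state one), indels (QC indel
handling is tested on constructed fixtures), X-chromosome dosage coding,
and genotype-level artifacts behind HWE/missingness (those columns are
consumed when present, never simulated).

## Numerical and scale choices

Problem sizes in the analysis scripts and tests are desk-scale by design:
2,000-variant panels for the pipeline narrative, 10,000-100,000 variants
where a calibration needs mass (null lambda_GC, correlation recovery),
100 replicates of n = 100,000 individual-level simulations for the
conditional-analysis oracle. Tolerances: IVW vs weighted-least-squares to
1e-12 relative; classifier closed forms vs adaptive quadrature to 1e-6 on
the log scale (the quadrature oracle integrates an exponent-shifted
integrand over a mode-centered window, with the mode located analytically
and the integral fully numeric); prediction intervals vs the textbook
formulas to 1e-10. Posterior vectors are renormalized after log-sum-exp so
they sum to 1 at machine precision. Coordinates are 1-based inclusive
throughout; alleles are uppercased before comparison.

## Known limitations

* The conditional analysis is plain z-conditioning; the original study's
  tool applies additional shrinkage internals, so equivalence is asserted
  against an individual-level regression oracle, not against that tool.
* The classifier treats c as a single global scalar (as in the study);
  per-variant heterogeneous correlations are out of scope.
* The BOTH-independent component uses exactly uncorrelated effects; some
  formulations put a small positive prior correlation there instead.
* LDSC slope estimation, functional annotation, TWAS/colocalization and
  gene prioritization are out of scope; only the bespoke statistics around
  them are implemented.
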