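# migwas

Post-GWAS analysis pipeline for a large migraine case-control
meta-analysis: cohort harmonization and QC, inverse-variance weighted
(IVW) fixed-effect meta-analysis with effective-sample-size control,
algorithmic risk-locus definition, stepwise conditional analysis from
summary statistics, and a four-model Bayesian classifier that decides
whether a risk allele is specific to migraine with aura (MA), specific to
migraine without aura (MO), shared, or null. It is written for statistical
geneticists who work with GWAS summary statistics rather than
individual-level data.

The real consortium inputs are access-controlled, so the package ships a
first-class synthetic-data generator that emulates multi-cohort summary
statistics (block LD, spike-and-slab effects, per-variant sample-size and
info variation, strand flips on ambiguous SNPs, and MO/MA estimators
correlated through shared controls) with known ground truth; every stage
is tested against it and against independent oracles.

## The statistics at the core

**Pooling and precision.** Cohort log-odds estimates combine as
`beta = Σ w_i b_i / Σ w_i`, `se = (Σ w_i)^(-1/2)` with `w_i = 1/se_i²`.
Per-variant precision is summarized by the effective sample size
`N_eff = 1/(f(1−f)·se²) ≈ 2·N·t(1−t)·I` (case proportion t, imputation
info I); variants with `N_eff < 5,000` are excluded, and inflation is
reported as `λ_GC = median(χ²)/qchisq(0.5, 1)`.

**Risk loci.** Greedy P-ordered clumping at `r² < 0.1` defines index
variants; intervals spanning all GWS variants at `r² > 0.6` with each
index are merged when closer than 250 kb; remaining GWS variants join
their nearest locus, boundaries update, and a final merge runs. Loci are
named by the nearest (protein-coding, else noncoding) gene, "Near"-prefixed
when the lead variant overlaps no transcript.

**Conditional analysis.** Within each locus, SNPs with `N_eff` within
±10% of the lead's are conditioned on the growing selected set via
reference LD, `z_c|s = (z_c − R_cs R_ss⁻¹ z_s)/√(1 − R_cs R_ss⁻¹ R_sc)`,
selecting while the conditional p stays below 5×10⁻⁸.

**Subtype classifier.** For paired subtype estimates with sampling
covariance `Σ = [[se₁², c·se₁se₂], [c·se₁se₂, se₂²]]` (estimator
correlation c = 0.148 from shared controls), the marginal likelihood of
model m is the bivariate normal density of the estimates at mean 0 with
covariance `Σ + P_m`, where `P_NULL = 0`, `P_MO = diag(τ², 0)`,
`P_MA = diag(0, τ²)` and BOTH mixes the fixed-effect (`τ²·J`) and
independent-effects (`τ²·I`) priors with equal weight, τ = 0.2 on the
log-odds scale. Posteriors under equal model priors label a variant when
one model exceeds 95%. A normal-approximation test of effect equality
accounts for c at the Bonferroni level 0.05/123.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on the
synthetic study (five cohorts with the study collections' case/control
counts over a 2,000-variant panel) and write their tables under
`results/`:

```sh
python analysis/01_simulate.py
python analysis/02_qc.py
python analysis/03_meta.py
python analysis/04_loci.py
python analysis/05_conditional.py
python analysis/06_subtype.py
python analysis/07_enrichment.py
```

Output of the meta-analysis and locus steps:

```
pooled 5 cohorts over 2000 variants; excluded 0 with N_eff < 5,000
lambda_GC = 1.162; 56 genome-wide significant variants
56 GWS variants -> 18 index variants -> 12 risk loci
```

With a 1% causal spike, λ_GC > 1 reflects true polygenic signal, not
confounding; the 56 genome-wide significant variants collapse to 18
LD-independent index variants and 12 merged risk loci, each named by its
nearest synthetic gene. The conditional step then reports

```
conditioned 12 loci; 2 secondary signal(s) remained genome-wide significant
```

i.e. two loci carry a second association that survives conditioning on
their lead variant. The subtype step estimates the estimator correlation
from a predominantly null variant set and classifies the lead-like set:

```
estimated estimator correlation c = 0.1604 (generator truth 0.148)
labels at 95% posterior: {'unresolved': 1494, 'BOTH': 314, 'MO': 99, 'MA': 93}
precision of assigned labels vs generating model: 0.980
```

Unresolved is the honest majority call at this noise level — the Bayes
factor toward an exactly-zero effect saturates near τ/se, so only variants
with strong, clean signals cross 95% — and 98% of the labels that are
assigned match the hidden generating model. The enrichment step flags the
deliberately inflated artery-like tissue outside its 95% leave-one-out
prediction interval and converts observed-scale heritabilities to the
liability scale at prevalence 16% and case proportion 11.7% (conversion
factor 2.9534).

The same operations are available as a CLI (`migwas simulate`,
`migwas qc`, `migwas meta`, `migwas loci`, `migwas condition`,
`migwas subtype`, `migwas enrich ...`); see `migwas --help`.

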